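"""Synthetic trial generator for aerial-culling welfare data.

The generator emulates the statistical structure the analysis assumes: four
ammunition types assigned to sorties in randomised blocks of four without
replacement; log-normal chase times; exponential times to insensibility with
an ammunition-specific rate; random right-censoring of TTI, recording a
uniform draw on (0, true TTI) as the observed minimum; a FAAST-style two-shot
minimum; and post-mortem examination of a ground-accessible subset, with
detected pellets binomially thinned from the fired count and allocated to
anatomical zones multinomially.  The mandatory thorax shot is honoured by
guaranteeing at least one detected thorax pellet on every examined shotgun
carcase.

The TTI rate can be specified directly per arm, or calibrated from the
probability of insensibility within 1 s of the first shot by solving
P(T <= 1) = 1 - exp(-rate) for the rate; exactly one of the two
specifications must be supplied.

A packaged configuration (:func:`trial_config`) regenerates a trial-like
dataset: 390 animals over 17 sorties, arm sizes 94-100, no escapes.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data_model import (
    Ammo,
    EncounterRecord,
    Exam,
    MASS_SCALE_LIMIT_KG,
    Outcome,
    PELLETS_PER_CARTRIDGE,
    PostMortemRecord,
    SHOTGUN_AMMO,
    SexAge,
    Zone,
    validate_encounters,
    validate_postmortem,
)

__all__ = [
    "SimulationConfig",
    "assign_ammo_to_sorties",
    "simulate_encounters",
    "simulate_postmortem",
    "simulate_trial",
    "trial_config",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def _ammo_map(raw: Mapping, what: str) -> dict[Ammo, float]:
    out = {}
    for k, v in raw.items():
        key = k if isinstance(k, Ammo) else Ammo(str(k))
        out[key] = float(v)
    missing = [a.value for a in Ammo if a not in out]
    if missing:
        raise ConfigError(f"{what} missing arm(s): {missing}")
    return out


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic trial.

    Defaults reflect the trial design: 17 two-hour sorties, right-censoring
    of roughly 23% of TTI observations, a fifth of carcases examined on the
    ground, and about 78% of fired shotgun pellets not recoverable on
    radiographs.
    """

    seed: int = 20230220
    n_sorties: int = 17
    animals_per_sortie: float = 23.0
    n_per_arm: dict[Ammo, int] | None = None
    ct_mu_log: float = math.log(60.0)
    ct_sigma_log: float = 0.8
    tti_rate_per_ammo: dict[Ammo, float] | None = None
    p_instant_per_ammo: dict[Ammo, float] | None = None
    censor_prob: float = 0.23
    shots_mean: float = 2.6
    pellet_hit_prob: float = 0.22
    zone_weights: dict[Zone, float] = field(
        default_factory=lambda: {
            Zone.HEAD: 0.05,
            Zone.NECK: 0.10,
            Zone.THORAX: 0.60,
            Zone.ABDOMEN: 0.15,
            Zone.LIMBS: 0.10,
        }
    )
    zone_scatter_per_ammo: dict[Ammo, float] = field(
        default_factory=lambda: {
            Ammo.RIFLE_308: 0.0,
            Ammo.BUCK_00: 0.15,
            Ammo.BUCK_1: 0.30,
            Ammo.BUCK_4: 0.50,
        }
    )
    postmortem_fraction: float = 0.20
    ex_situ_fraction: float = 0.78
    group_mean_size: float = 3.33
    sex_age_probs: dict[SexAge, float] = field(
        default_factory=lambda: {
            SexAge.ADULT_M: 0.68,
            SexAge.ADULT_F: 0.20,
            SexAge.YEARLING: 0.07,
            SexAge.FAWN: 0.05,
        }
    )
    mass_mean_kg: float = 68.5
    mass_sd_kg: float = 20.4

    def __post_init__(self) -> None:
        if self.n_sorties < 1:
            raise ConfigError("n_sorties must be >= 1")
        if self.tti_rate_per_ammo is not None and self.p_instant_per_ammo is not None:
            raise ConfigError(
                "specify the TTI exponential via rates or instant-kill "
                "probabilities, not both"
            )
        if self.tti_rate_per_ammo is None and self.p_instant_per_ammo is None:
            # fixture convention: per-arm instant-kill probabilities
            self.p_instant_per_ammo = {
                Ammo.RIFLE_308: 0.07,
                Ammo.BUCK_00: 0.03,
                Ammo.BUCK_1: 0.05,
                Ammo.BUCK_4: 0.05,
            }
        if self.tti_rate_per_ammo is not None:
            self.tti_rate_per_ammo = _ammo_map(self.tti_rate_per_ammo, "tti_rate_per_ammo")
            if any(v <= 0 for v in self.tti_rate_per_ammo.values()):
                raise ConfigError("TTI rates must be > 0")
        if self.p_instant_per_ammo is not None:
            self.p_instant_per_ammo = _ammo_map(self.p_instant_per_ammo, "p_instant_per_ammo")
            if any(not 0 < v < 1 for v in self.p_instant_per_ammo.values()):
                raise ConfigError("instant-kill probabilities must be in (0, 1)")
        for name in ("censor_prob", "pellet_hit_prob", "postmortem_fraction",
                     "ex_situ_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_arm is not None:
            self.n_per_arm = {
                (k if isinstance(k, Ammo) else Ammo(str(k))): int(v)
                for k, v in self.n_per_arm.items()
            }
            if any(v < 0 for v in self.n_per_arm.values()):
                raise ConfigError("n_per_arm counts must be >= 0")
        if self.shots_mean < 2:
            raise ConfigError("shots_mean must be >= 2 (two-shot minimum)")
        self.zone_weights = {
            (k if isinstance(k, Zone) else Zone(str(k))): float(v)
            for k, v in self.zone_weights.items()
        }
        if any(v < 0 for v in self.zone_weights.values()):
            raise ConfigError("zone weights must be non-negative")
        if sum(self.zone_weights.values()) <= 0:
            raise ConfigError("zone weights must sum to > 0")
        self.zone_scatter_per_ammo = _ammo_map(
            self.zone_scatter_per_ammo, "zone_scatter_per_ammo"
        )
        if any(not 0 <= v <= 1 for v in self.zone_scatter_per_ammo.values()):
            raise ConfigError("zone scatter values must be in [0, 1]")
        self.sex_age_probs = {
            (k if isinstance(k, SexAge) else SexAge(str(k))): float(v)
            for k, v in self.sex_age_probs.items()
        }
        if not math.isclose(sum(self.sex_age_probs.values()), 1.0, abs_tol=1e-6):
            raise ConfigError("sex_age_probs must sum to 1")

    def tti_rates(self) -> dict[Ammo, float]:
        """Per-arm exponential TTI rates (per second)."""
        if self.tti_rate_per_ammo is not None:
            return dict(self.tti_rate_per_ammo)
        assert self.p_instant_per_ammo is not None
        return {a: -math.log1p(-p) for a, p in self.p_instant_per_ammo.items()}

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(raw))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)


def assign_ammo_to_sorties(n_sorties: int, seed: int | np.random.Generator) -> list[Ammo]:
    """Randomised-block ammunition assignment: permuted blocks of all four types.

    Each consecutive block of four sorties receives an independent random
    permutation of the four ammunition types (the final block is truncated if
    ``n_sorties`` is not a multiple of four).
    """
    if n_sorties < 1:
        raise ConfigError("n_sorties must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[Ammo] = []
    arms = list(Ammo)
    while len(out) < n_sorties:
        out.extend(arms[i] for i in rng.permutation(4))
    return out[:n_sorties]


def _sortie_counts(config: SimulationConfig, ammo_seq: list[Ammo], rng) -> np.ndarray:
    """Animals per sortie; arm totals fixed when ``n_per_arm`` is given."""
    n_sorties = config.n_sorties
    if config.n_per_arm is None:
        counts = rng.poisson(config.animals_per_sortie, size=n_sorties)
        if counts.sum() == 0:
            counts[0] = 1
        return counts
    counts = np.zeros(n_sorties, dtype=int)
    for arm, total in config.n_per_arm.items():
        slots = [i for i, a in enumerate(ammo_seq) if a is arm]
        if not slots and total > 0:
            raise ConfigError(f"n_per_arm for {arm.value} but no sortie has that arm")
        if slots:
            split = rng.multinomial(total, np.full(len(slots), 1.0 / len(slots)))
            counts[slots] = split
    return counts


def simulate_encounters(
    config: SimulationConfig,
    return_latent: bool = False,
):
    """Generate encounter records; optionally also the latent true TTIs.

    Chase times are log-normal; true TTIs are exponential at the arm's rate;
    an animal whose true TTI is at most 1 s is recorded as immediately
    insensible.  Censoring emulates the observer losing sight of the animal:
    an independent out-of-view time is drawn as Exp(rate * c / (1 - c)) with
    c = ``censor_prob``, so that a fraction c of animals goes out of view
    before insensibility.  Such rows record the out-of-view time as the
    observed minimum and are flagged censored.  Independence of the
    out-of-view process from the insensibility process is what keeps the
    right-censored likelihood (and hence the downstream survival fits)
    calibrated; censoring mechanisms whose recorded minimum depends on the
    true event time (for example a uniform fraction of it) are informative
    and bias the fitted rates.
    """
    rng = np.random.default_rng(config.seed)
    ammo_seq = assign_ammo_to_sorties(config.n_sorties, rng)
    counts = _sortie_counts(config, ammo_seq, rng)
    rates = config.tti_rates()
    sex_ages = list(config.sex_age_probs)
    sex_probs = np.array([config.sex_age_probs[sa] for sa in sex_ages])

    records: list[EncounterRecord] = []
    latents: list[float] = []
    animal_no = 0
    group_no = 0
    for sortie in range(config.n_sorties):
        arm = ammo_seq[sortie]
        n_here = int(counts[sortie])
        remaining = n_here
        while remaining > 0:
            group_no += 1
            size = min(remaining, 1 + rng.poisson(max(config.group_mean_size - 1, 0)))
            for _ in range(size):
                animal_no += 1
                ct = float(np.exp(config.ct_mu_log + config.ct_sigma_log * rng.standard_normal()))
                true_tti = float(rng.exponential(1.0 / rates[arm]))
                if true_tti <= 1.0:
                    outcome = Outcome.INSENSIBLE_LE_1S
                    tti, censored = max(true_tti, 0.01), False
                else:
                    outcome = Outcome.INSENSIBLE_GT_1S
                    c = config.censor_prob
                    out_of_view = (
                        float(rng.exponential((1.0 - c) / (rates[arm] * c)))
                        if c > 0 else math.inf
                    )
                    if out_of_view < true_tti:
                        tti, censored = out_of_view, True
                    else:
                        tti, censored = true_tti, False
                shots = 2 + int(rng.poisson(config.shots_mean - 2.0))
                records.append(
                    EncounterRecord(
                        animal_id=f"D{animal_no:04d}",
                        sortie_id=sortie + 1,
                        group_id=group_no,
                        ammo=arm,
                        ct_s=round(ct, 1),
                        tti_s=round(tti, 1) if censored or true_tti > 1 else round(tti, 2),
                        tti_censored=censored,
                        shots_fired=shots,
                        outcome=outcome,
                        sex_age=sex_ages[int(rng.choice(len(sex_ages), p=sex_probs))],
                    )
                )
                latents.append(true_tti)
            remaining -= size
    # rounding a censored minimum up could place it above the latent value
    for rec, true_tti in zip(records, latents):
        if rec.tti_censored and rec.tti_s >= true_tti:
            rec.tti_s = max(0.0, round(true_tti - 0.05, 2))
    validate_encounters(records)
    if return_latent:
        return records, np.array(latents)
    return records


def simulate_postmortem(
    encounters: Sequence[EncounterRecord],
    config: SimulationConfig,
) -> list[PostMortemRecord]:
    """Generate post-mortem records for a ground-examined subset of kills.

    For each examined shotgun kill, detected pellets are binomially thinned
    from the fired count at ``pellet_hit_prob`` (at least one, reflecting the
    mandatory thorax shot), allocated to zones multinomially by
    ``zone_weights``, and one pellet is reassigned to the thorax when none
    landed there.  Cartridges with more (and lighter) pellets pattern more
    widely, so the per-arm ``zone_scatter_per_ammo`` fraction blends the
    aim-point weights towards a uniform spread over the zones; thorax
    concentration therefore declines as pellets per cartridge increase.
    Wound tracts equal detected pellets for shotgun kills and shots fired
    for rifle kills.
    """
    rng = np.random.default_rng(config.seed + 1)
    zones = list(Zone)
    base = np.array([config.zone_weights[z] for z in zones], dtype=float)
    base = base / base.sum()
    arm_weights = {
        a: (1.0 - g) * base + g / len(zones)
        for a, g in config.zone_scatter_per_ammo.items()
    }
    thorax_i = zones.index(Zone.THORAX)
    records: list[PostMortemRecord] = []
    for enc in encounters:
        if enc.outcome in (Outcome.WOUNDED_ESCAPED, Outcome.MISSED_ESCAPED):
            continue
        if rng.random() >= config.postmortem_fraction:
            continue
        exam = Exam.EX_SITU if rng.random() < config.ex_situ_fraction else Exam.IN_SITU_ONLY
        mass = float(rng.normal(config.mass_mean_kg, config.mass_sd_kg))
        mass = max(mass, 17.0)
        censored_mass = mass > MASS_SCALE_LIMIT_KG
        mass_val = MASS_SCALE_LIMIT_KG if censored_mass else round(mass, 1)
        if enc.ammo is Ammo.RIFLE_308:
            per_zone = {z: 0 for z in zones}
            records.append(
                PostMortemRecord(
                    animal_id=enc.animal_id,
                    wound_tracts=enc.shots_fired,
                    pellets_by_zone=per_zone,
                    pellets_expected=0,
                    body_mass_kg=mass_val,
                    mass_censored=censored_mass,
                    exam=exam,
                )
            )
            continue
        expected = enc.shots_fired * PELLETS_PER_CARTRIDGE[enc.ammo]
        detected = int(rng.binomial(expected, config.pellet_hit_prob))
        detected = max(detected, 1)  # the mandatory thorax shot always lands
        alloc = rng.multinomial(detected, arm_weights[enc.ammo])
        if alloc[thorax_i] == 0:
            donor = int(np.argmax(alloc))
            alloc[donor] -= 1
            alloc[thorax_i] += 1
        records.append(
            PostMortemRecord(
                animal_id=enc.animal_id,
                wound_tracts=detected,
                pellets_by_zone={z: int(c) for z, c in zip(zones, alloc)},
                pellets_expected=expected,
                body_mass_kg=mass_val,
                mass_censored=censored_mass,
                exam=exam,
            )
        )
    validate_postmortem(records, encounters)
    return records


def simulate_trial(config: SimulationConfig | None = None):
    """Generate the encounter and post-mortem tables in one call."""
    config = config or trial_config()
    enc = simulate_encounters(config)
    pm = simulate_postmortem(enc, config)
    return enc, pm


def trial_config() -> SimulationConfig:
    """The packaged trial-like configuration (390 animals, 17 sorties)."""
    ref = importlib.resources.files("cullwelfare") / "fixtures" / "trial_config.yaml"
    raw = yaml.safe_load(ref.read_text())
    return SimulationConfig.from_dict(raw)
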