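"""Synthetic canine cohorts with the study's group structure.

The experimental design is five groups of five beagles: a healthy control
group and four groups injected with CCl4 for 1-4 months to stage
progressively severe hepatic fibrosis and portal hypertension.  Published
group summaries (mean +/- SD) cover invasive free portal pressure (FPP,
mmHg), per-vessel inner diameters (mm) and per-vessel maximum Doppler
velocities (cm/s); those summaries parameterise the generator verbatim.

Every quantity is drawn independently from a Normal(mean, SD) truncated at
zero (strict positivity); group membership alone carries the correlation
between disease stage and all quantities, because no covariances are
published.  Two modes:

``table_emulation``
    Mirrors the study design: the invasive FPP truth is drawn from its own
    published distribution, statistically linked to the Doppler measurements
    only through group membership.

``forward_consistent``
    Truth produced by the forward model itself: the animal's FPP draw
    becomes its absolute reference pressure ``p_ref`` and
    ``fpp_true = p_ref + gauge trunk pressure`` computed from the noise-free
    measurements.  The full pipeline applied to noise-free data then
    recovers ``fpp_true`` exactly, which makes parameter-recovery
    experiments well-posed.

Blood density and viscosity are not published; defaults are typical
mammalian whole-blood values (1050 +/- 15 kg/m^3, 3.5e-3 +/- 0.3e-3 Pa s).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .doppler_bc import DopplerMeasurement
from .errors import ConfigurationError, ParameterError, ValidationError

GROUP_LABELS = ["Control", "CCl4_1mo", "CCl4_2mo", "CCl4_3mo", "CCl4_4mo"]

#: Invasive free portal pressure (mmHg), mean and SD per group.
FPP_MMHG = {
    "Control": (6.6, 1.1),
    "CCl4_1mo": (10.0, 1.6),
    "CCl4_2mo": (13.6, 1.5),
    "CCl4_3mo": (15.6, 4.0),
    "CCl4_4mo": (19.2, 1.9),
}

#: Inner vessel diameters (mm), mean and SD per vessel per group.
DIAMETERS_MM = {
    "portal_vein":          {"Control": (4.5, 0.4), "CCl4_1mo": (7.2, 0.6), "CCl4_2mo": (7.7, 1.2), "CCl4_3mo": (8.2, 1.0), "CCl4_4mo": (9.5, 1.3)},
    "left_portal":          {"Control": (3.4, 0.3), "CCl4_1mo": (4.9, 0.7), "CCl4_2mo": (5.9, 0.9), "CCl4_3mo": (6.2, 1.4), "CCl4_4mo": (7.6, 1.2)},
    "right_portal":         {"Control": (4.2, 0.2), "CCl4_1mo": (4.9, 0.4), "CCl4_2mo": (5.2, 0.6), "CCl4_3mo": (5.8, 0.6), "CCl4_4mo": (6.8, 1.2)},
    "splenic":              {"Control": (1.8, 0.2), "CCl4_1mo": (3.4, 0.5), "CCl4_2mo": (4.0, 0.5), "CCl4_3mo": (4.5, 0.7), "CCl4_4mo": (4.9, 0.8)},
    "superior_mesenteric":  {"Control": (3.1, 0.3), "CCl4_1mo": (4.1, 0.2), "CCl4_2mo": (4.8, 0.5), "CCl4_3mo": (5.8, 0.7), "CCl4_4mo": (6.0, 0.6)},
    "inferior_mesenteric":  {"Control": (2.0, 0.1), "CCl4_1mo": (2.4, 0.3), "CCl4_2mo": (2.9, 0.3), "CCl4_3mo": (3.5, 0.4), "CCl4_4mo": (3.8, 0.4)},
}

#: Maximum Doppler velocities (cm/s), mean and SD per vessel per group.
VELOCITIES_CM_S = {
    "portal_vein":          {"Control": (33.8, 8.7), "CCl4_1mo": (30.6, 6.3), "CCl4_2mo": (24.8, 3.7), "CCl4_3mo": (25.1, 1.5), "CCl4_4mo": (22.0, 1.6)},
    "left_portal":          {"Control": (22.6, 4.4), "CCl4_1mo": (23.2, 2.9), "CCl4_2mo": (13.7, 3.4), "CCl4_3mo": (11.4, 2.3), "CCl4_4mo": (9.7, 0.5)},
    "right_portal":         {"Control": (24.2, 4.2), "CCl4_1mo": (25.4, 1.3), "CCl4_2mo": (14.5, 4.9), "CCl4_3mo": (11.7, 2.1), "CCl4_4mo": (10.6, 0.6)},
    "splenic":              {"Control": (16.5, 2.3), "CCl4_1mo": (16.5, 2.0), "CCl4_2mo": (13.8, 2.9), "CCl4_3mo": (18.5, 6.5), "CCl4_4mo": (13.7, 2.2)},
    "superior_mesenteric":  {"Control": (27.3, 4.3), "CCl4_1mo": (27.5, 4.5), "CCl4_2mo": (18.0, 0.9), "CCl4_3mo": (17.7, 2.3), "CCl4_4mo": (16.5, 3.0)},
    "inferior_mesenteric":  {"Control": (15.0, 1.6), "CCl4_1mo": (13.0, 1.6), "CCl4_2mo": (10.7, 1.8), "CCl4_3mo": (11.1, 1.1), "CCl4_4mo": (10.3, 0.5)},
}

DEFAULT_DENSITY_KG_M3 = (1050.0, 15.0)
DEFAULT_VISCOSITY_PA_S = (3.5e-3, 0.3e-3)

DENSITY_RANGE = (900.0, 1200.0)
VISCOSITY_RANGE = (1e-3, 1e-2)


@dataclass(frozen=True)
class BloodProperties:
    """Whole-blood density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float
    viscosity: float
    allow_out_of_range: bool = False

    def __post_init__(self):
        if self.allow_out_of_range:
            return
        if not (DENSITY_RANGE[0] <= self.density <= DENSITY_RANGE[1]):
            raise ValidationError(
                f"density {self.density} kg/m^3 outside {DENSITY_RANGE}; "
                "set allow_out_of_range=True to override"
            )
        if not (VISCOSITY_RANGE[0] <= self.viscosity <= VISCOSITY_RANGE[1]):
            raise ValidationError(
                f"viscosity {self.viscosity} Pa s outside {VISCOSITY_RANGE}; "
                "set allow_out_of_range=True to override"
            )


@dataclass(frozen=True)
class GroupParams:
    """Published mean/SD summaries for one experimental group."""

    label: str
    fpp_mmhg: tuple[float, float]
    diameters_mm: dict[str, tuple[float, float]]
    velocities_cm_s: dict[str, tuple[float, float]]
    density_kg_m3: tuple[float, float] = DEFAULT_DENSITY_KG_M3
    viscosity_pa_s: tuple[float, float] = DEFAULT_VISCOSITY_PA_S

    def __post_init__(self):
        pairs = [self.fpp_mmhg, self.density_kg_m3, self.viscosity_pa_s]
        pairs += list(self.diameters_mm.values()) + list(self.velocities_cm_s.values())
        for mean, sd in pairs:
            if not (mean > 0) or sd < 0:
                raise ValidationError(f"group {self.label}: mean {mean} must be > 0, SD {sd} >= 0")


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    group: str
    doppler: tuple[DopplerMeasurement, ...]
    blood: BloodProperties
    fpp_true_mmhg: float
    p_ref_mmhg: float | None = None  # forward_consistent baseline, else None

    def __post_init__(self):
        if not (self.fpp_true_mmhg > 0):
            raise ValidationError(f"animal {self.animal_id}: fpp_true must be > 0")
        vessels = [m.vessel for m in self.doppler]
        if len(vessels) != len(set(vessels)):
            raise ValidationError(f"animal {self.animal_id}: duplicate vessel measurement")


@dataclass
class Cohort:
    records: list[AnimalRecord]
    seed: int
    mode: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for m in r.doppler:
                rows.append(
                    {
                        "animal_id": r.animal_id, "group": r.group, "vessel": m.vessel,
                        "d_us_mm": m.d_us_mm, "vmax_cm_s": m.v_max_cm_s,
                        "rho": r.blood.density, "mu": r.blood.viscosity,
                        "fpp_true_mmHg": r.fpp_true_mmhg,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        out = []
        for r in self.records:
            d = {
                "animal_id": r.animal_id, "group": r.group,
                "blood": {"density": r.blood.density, "viscosity": r.blood.viscosity},
                "fpp_true_mmHg": r.fpp_true_mmhg,
                "p_ref_mmHg": r.p_ref_mmhg,
                "doppler": [asdict(m) for m in r.doppler],
            }
            out.append(d)
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "mode": self.mode, "animals": out}, fh, indent=1)


def default_group_params() -> list[GroupParams]:
    """The five groups parameterised by the published summary tables."""
    return [
        GroupParams(
            label=g,
            fpp_mmhg=FPP_MMHG[g],
            diameters_mm={v: DIAMETERS_MM[v][g] for v in DIAMETERS_MM},
            velocities_cm_s={v: VELOCITIES_CM_S[v][g] for v in VELOCITIES_CM_S},
        )
        for g in GROUP_LABELS
    ]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float, upper: float = np.inf) -> float:
    """One Normal(mean, sd) draw conditioned on (lower, upper) by rejection.

    Published CVs keep the truncation point several SDs from the mean, so
    acceptance is near-certain and the bias negligible.
    """
    if sd == 0:
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lower < x < upper:
            return x
    raise ParameterError(
        f"truncated-normal rejection failed for mean={mean}, sd={sd}, bounds=({lower}, {upper})"
    )


def generate_cohort(
    params: list[GroupParams],
    n_per_group: int,
    seed: int,
    mode: str = "table_emulation",
    tree=None,
    truncate_frac: float = 0.0,
    mean_factor: float = 0.7,
) -> Cohort:
    """Draw a cohort of ``n_per_group`` animals per group.

    Deterministic: each animal draws from its own child generator keyed by
    (seed, group index, animal index), so enlarging the cohort never
    perturbs earlier animals.  ``truncate_frac`` sets the lower truncation
    bound as a fraction of each mean (default 0 = positivity only).

    In ``forward_consistent`` mode a valid ``tree`` is required and
    ``fpp_true`` is produced by :func:`forward_truth`.
    """
    if not params:
        raise ConfigurationError("empty group-parameter list")
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    if mode not in ("table_emulation", "forward_consistent"):
        raise ConfigurationError(f"unknown cohort mode {mode!r}")
    if mode == "forward_consistent" and tree is None:
        raise ConfigurationError("forward_consistent mode requires a vessel tree")

    records: list[AnimalRecord] = []
    for gi, gp in enumerate(params):
        for ai in range(n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(gi, ai))
            )
            fpp = _trunc_normal(rng, *gp.fpp_mmhg, lower=truncate_frac * gp.fpp_mmhg[0])
            rho = _trunc_normal(
                rng, *gp.density_kg_m3,
                lower=max(truncate_frac * gp.density_kg_m3[0], DENSITY_RANGE[0]),
                upper=DENSITY_RANGE[1],
            )
            mu = _trunc_normal(
                rng, *gp.viscosity_pa_s,
                lower=max(truncate_frac * gp.viscosity_pa_s[0], VISCOSITY_RANGE[0]),
                upper=VISCOSITY_RANGE[1],
            )
            doppler = []
            for vessel in sorted(gp.diameters_mm):
                d = _trunc_normal(rng, *gp.diameters_mm[vessel],
                                  lower=truncate_frac * gp.diameters_mm[vessel][0])
                v = _trunc_normal(rng, *gp.velocities_cm_s[vessel],
                                  lower=truncate_frac * gp.velocities_cm_s[vessel][0])
                doppler.append(DopplerMeasurement(vessel=vessel, d_us_mm=d, v_max_cm_s=v))
            record = AnimalRecord(
                animal_id=f"{gp.label}_{ai + 1:02d}",
                group=gp.label,
                doppler=tuple(doppler),
                blood=BloodProperties(density=rho, viscosity=mu),
                fpp_true_mmhg=fpp,
                p_ref_mmhg=None,
            )
            if mode == "forward_consistent":
                p_ref = fpp
                truth = forward_truth(record, tree, p_ref, mean_factor=mean_factor)
                record = replace(record, fpp_true_mmhg=truth, p_ref_mmhg=p_ref)
            records.append(record)
    return Cohort(records=records, seed=seed, mode=mode)


def simulate_blood_density(
    true_density: float, n_repeats: int = 3, noise_sd: float = 5.0, seed: int | None = None
) -> float:
    """Emulate the bench protocol: weigh a 1 mL aliquot ``n_repeats`` times
    (>= 3 per protocol) on a noisy balance and average, reported in kg/m^3.

    ``noise_sd`` is the per-weighing SD expressed on the kg/m^3 scale (a
    balance SD of 5 mg on a ~1.05 g aliquot maps to 5 kg/m^3).
    """
    if n_repeats < 3:
        raise ParameterError(f"protocol floor: n_repeats >= 3, got {n_repeats}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    weighings = true_density + noise_sd * rng.standard_normal(n_repeats)
    return float(np.mean(weighings))


def forward_truth(record: AnimalRecord, tree, p_ref_mmhg: float, mean_factor: float = 0.7) -> float:
    """Run the Doppler-BC + network-solve forward model on the record's
    (noise-free) measurements and return ``p_ref + gauge trunk midpoint`` in
    mmHg.  By construction the pipeline applied to the same noise-free data
    returns exactly this value."""
    from .doppler_bc import assemble_bcs
    from .flow_solver import SolverConfig, extract_vfpp, solve_network

    bcs = assemble_bcs(record, tree, mean_factor=mean_factor)
    solution = solve_network(tree, bcs, record.blood)
    return extract_vfpp(solution, tree, SolverConfig(p_ref_mmhg=p_ref_mmhg))


def add_doppler_noise(
    record: AnimalRecord, cv_diameter: float, cv_velocity: float, seed: int | None = None
) -> AnimalRecord:
    """Observer-variability model: multiply each diameter and velocity by an
    independent Normal(1, cv) factor truncated positive.  Reported observer
    variability bounds the defaults at CV <= 0.10."""
    if cv_diameter < 0 or cv_velocity < 0:
        raise ParameterError("noise CVs must be >= 0")
    if cv_diameter == 0 and cv_velocity == 0:
        return record
    rng = np.random.default_rng(seed)
    noisy = []
    for m in record.doppler:
        fd = _trunc_normal(rng, 1.0, cv_diameter, lower=0.0)
        fv = _trunc_normal(rng, 1.0, cv_velocity, lower=0.0)
        noisy.append(replace(m, d_us_mm=m.d_us_mm * fd, v_max_cm_s=m.v_max_cm_s * fv))
    return replace(record, doppler=tuple(noisy))
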