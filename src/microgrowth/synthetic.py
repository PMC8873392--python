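"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a birth-cohort microbiota/growth
study: stool samples at five time points (1 m, 3 m, 4 m, 6 y, 10 y) and
anthropometry at eight (1 m, 3 m, 4 m, 2 y, 6 y, 7 y, 10 y, 12 y).

Genus counts are Dirichlet-multinomial draws whose concentration profiles
shift with age: infancy is Bifidobacterium-dominated (phylum
Actinobacteria) with Bacteroidetes nearly absent — so the F/B ratio is
undefined for most infant samples — while childhood is
Firmicutes-dominated with Bacteroidetes around 10-20%.

zBMI trajectories follow a first-order autoregression with a per-subject
random intercept, a standardized-birthweight slope, and optional planted
linear effects of the previous time point's CLR genus abundances:

    zBMI(T) = ar * zBMI(T-1) + sum_g beta_g * CLRz_g(T-1)
              + b_bw * bw_z + u_subject + eps

where ``CLRz`` is the CLR of the latent (true) composition, standardized
across subjects within each time point so planted slopes are per-SD, and
the genus term applies where the preceding anthropometry time point has a
stool sample (1m->3m, 3m->4m, 4m->2y, 6y->7y, 10y->12y).

Weight and length consistent with the generated zBMI are produced by
inverting the LMS transform against a synthetic growth reference, so the
anthropometry stage can be exercised end to end.  Everything is
reproducible from the config seed; planted truths are retained for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .anthropometry import inverse_lms, synthetic_reference
from .compositions import DEFAULT_SCFA_PRODUCERS, TaxonTable, clr

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "apply_missingness",
    "DEFAULT_GENUS_CATALOG",
    "STOOL_TIMEPOINTS",
    "ANTHRO_TIMEPOINTS",
    "TIMEPOINT_AGE_DAYS",
]

STOOL_TIMEPOINTS = ("1m", "3m", "4m", "6y", "10y")
ANTHRO_TIMEPOINTS = ("1m", "3m", "4m", "2y", "6y", "7y", "10y", "12y")
TIMEPOINT_AGE_DAYS = {
    "1m": 30,
    "3m": 91,
    "4m": 122,
    "2y": 730,
    "6y": 2191,
    "7y": 2556,
    "10y": 3652,
    "12y": 4383,
}
INFANT_TIMEPOINTS = frozenset({"1m", "3m", "4m"})

# genus -> phylum; the curated SCFA producers plus common non-producer genera
DEFAULT_GENUS_CATALOG: tuple[tuple[str, str], ...] = tuple(
    (g, p) for g, p, _m in DEFAULT_SCFA_PRODUCERS
) + (
    ("Ruminococcus_2", "Firmicutes"),
    ("Lachnospira", "Firmicutes"),
    ("Streptococcus", "Firmicutes"),
    ("Veillonella", "Firmicutes"),
    ("Clostridium sensu stricto 1", "Firmicutes"),
    ("Lactobacillus", "Firmicutes"),
    ("Parabacteroides", "Bacteroidetes"),
    ("Escherichia-Shigella", "Proteobacteria"),
    ("Collinsella", "Actinobacteria"),
)

# Mean relative-abundance profiles per time point.  Infancy:
# Bifidobacterium-dominated, Bacteroidetes ~1% (mostly absent per sample);
# childhood: Firmicutes ~0.6-0.7, Bacteroidetes 0.1-0.2, SCFA producers
# ~0.6 of the community.  Unlisted catalog genera get a small floor.
_PROFILE_MEANS: dict[str, dict[str, float]] = {
    "1m": {
        "Bifidobacterium": 0.45, "Collinsella": 0.03,
        "Escherichia-Shigella": 0.14, "Desulfovibrio": 0.004,
        "Akkermansia": 0.004,
        "Blautia": 0.05, "Faecalibacterium": 0.010, "Anaerostipes": 0.020,
        "Eubacterium hallii group": 0.020, "Subdoligranulum": 0.012,
        "Streptococcus": 0.065, "Veillonella": 0.045,
        "Clostridium sensu stricto 1": 0.018, "Lactobacillus": 0.012,
        "Bacteroides": 0.005, "Prevotella": 0.001, "Alistipes": 0.002,
        "Parabacteroides": 0.002,
    },
    "3m": {
        "Bifidobacterium": 0.52, "Collinsella": 0.03,
        "Escherichia-Shigella": 0.12, "Desulfovibrio": 0.004,
        "Akkermansia": 0.006,
        "Blautia": 0.04, "Faecalibacterium": 0.010, "Anaerostipes": 0.018,
        "Eubacterium hallii group": 0.018, "Subdoligranulum": 0.010,
        "Streptococcus": 0.055, "Veillonella": 0.040,
        "Clostridium sensu stricto 1": 0.014, "Lactobacillus": 0.010,
        "Bacteroides": 0.005, "Prevotella": 0.001, "Alistipes": 0.002,
        "Parabacteroides": 0.002,
    },
    "4m": {
        "Bifidobacterium": 0.57, "Collinsella": 0.028,
        "Escherichia-Shigella": 0.10, "Desulfovibrio": 0.004,
        "Akkermansia": 0.008,
        "Blautia": 0.038, "Faecalibacterium": 0.012, "Anaerostipes": 0.016,
        "Eubacterium hallii group": 0.016, "Subdoligranulum": 0.010,
        "Streptococcus": 0.048, "Veillonella": 0.034,
        "Clostridium sensu stricto 1": 0.012, "Lactobacillus": 0.008,
        "Bacteroides": 0.005, "Prevotella": 0.001, "Alistipes": 0.002,
        "Parabacteroides": 0.002,
    },
    "6y": {
        "Bifidobacterium": 0.08, "Collinsella": 0.05,
        "Escherichia-Shigella": 0.035, "Desulfovibrio": 0.005,
        "Akkermansia": 0.02,
        "Faecalibacterium": 0.08, "Blautia": 0.05, "Anaerostipes": 0.03,
        "Eubacterium rectale group": 0.05, "Eubacterium hallii group": 0.02,
        "Roseburia": 0.03, "Subdoligranulum": 0.04, "Coprococcus": 0.02,
        "Dialister": 0.02, "Holdemanella": 0.01,
        "Phascolarctobacterium": 0.01,
        "Ruminococcus_2": 0.10, "Lachnospira": 0.06, "Streptococcus": 0.04,
        "Veillonella": 0.02, "Clostridium sensu stricto 1": 0.03,
        "Lactobacillus": 0.02,
        "Bacteroides": 0.10, "Prevotella": 0.03, "Alistipes": 0.03,
        "Parabacteroides": 0.02,
    },
    "10y": {
        "Bifidobacterium": 0.06, "Collinsella": 0.05,
        "Escherichia-Shigella": 0.025, "Desulfovibrio": 0.005,
        "Akkermansia": 0.02,
        "Faecalibacterium": 0.09, "Blautia": 0.06, "Anaerostipes": 0.03,
        "Eubacterium rectale group": 0.05, "Eubacterium hallii group": 0.02,
        "Roseburia": 0.03, "Subdoligranulum": 0.05, "Coprococcus": 0.02,
        "Dialister": 0.02, "Holdemanella": 0.01,
        "Phascolarctobacterium": 0.01,
        "Ruminococcus_2": 0.13, "Lachnospira": 0.07, "Streptococcus": 0.05,
        "Veillonella": 0.03, "Clostridium sensu stricto 1": 0.04,
        "Lactobacillus": 0.02,
        "Bacteroides": 0.06, "Prevotella": 0.02, "Alistipes": 0.02,
        "Parabacteroides": 0.01,
    },
}
# total Dirichlet concentration: low in infancy (heavy overdispersion, most
# infant samples lack Bacteroidetes entirely), higher in childhood
_PROFILE_ALPHA0 = {"1m": 6.0, "3m": 6.0, "4m": 6.0, "6y": 30.0, "10y": 30.0}


def _default_profiles(catalog) -> dict[str, np.ndarray]:
    genera = [g for g, _p in catalog]
    floor = 1e-4
    profiles = {}
    for tp, means in _PROFILE_MEANS.items():
        v = np.array([means.get(g, floor) for g in genera], dtype=float)
        v = v / v.sum() * _PROFILE_ALPHA0[tp]
        profiles[tp] = v
    return profiles


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_subjects: int = 200
    stool_timepoints: tuple[str, ...] = STOOL_TIMEPOINTS
    anthro_timepoints: tuple[str, ...] = ANTHRO_TIMEPOINTS
    genus_catalog: tuple[tuple[str, str], ...] = DEFAULT_GENUS_CATALOG
    composition_profiles: dict[str, np.ndarray] | None = None
    library_size: float = 20_000.0
    library_size_sigma: float = 0.4  # sd of log library size
    effect_vector: dict[str, float] = field(default_factory=dict)
    effect_timepoints: tuple[str, ...] | None = None  # restrict genus effects to these stool tps
    zbmi_ar: float = 0.5
    birthweight_effect: float = 0.1
    birthweight_mean_g: float = 3613.0
    birthweight_sd_g: float = 477.0
    subject_intercept_sd: float = 0.3
    noise_sd: float = 0.5
    missing_rate_stool: float = 0.0
    missing_rate_anthro: float = 0.0
    missing_mechanism: str = "MCAR"  # or "MAR-on-zBMI"
    mar_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.composition_profiles is None:
            self.composition_profiles = _default_profiles(self.genus_catalog)
        genera = [g for g, _p in self.genus_catalog]
        if len(set(genera)) != len(genera):
            raise ValueError("duplicate genera in catalog")
        for tp in self.stool_timepoints:
            if tp not in self.composition_profiles:
                raise ValueError(f"no composition profile for time point {tp!r}")
            conc = np.asarray(self.composition_profiles[tp], float)
            if conc.shape != (len(genera),):
                raise ValueError(
                    f"profile for {tp!r} has length {conc.shape}, "
                    f"catalog has {len(genera)} genera"
                )
            if (conc <= 0).any():
                raise ValueError("concentration vectors must be strictly positive")
        for rate in (self.missing_rate_stool, self.missing_rate_anthro):
            if not 0 <= rate < 1:
                raise ValueError("missing rates must be in [0, 1)")
        if not abs(self.zbmi_ar) < 1:
            raise ValueError("|zbmi_ar| must be < 1")
        if self.library_size < 100:
            raise ValueError("library_size must be >= 100")
        unknown = set(self.effect_vector) - set(genera)
        if unknown:
            raise ValueError(f"effect_vector genera not in catalog: {sorted(unknown)}")
        if not set(self.stool_timepoints) <= set(self.anthro_timepoints):
            raise ValueError("stool time points must be a subset of anthro time points")


@dataclass
class SyntheticCohort:
    """Generated cohort: anthropometry, per-time-point taxon tables, truths."""

    cohort: pd.DataFrame
    taxon_tables: dict[str, TaxonTable]
    truth: dict

    def sample_id(self, subject: str, timepoint: str) -> str:
        return f"{subject}_{timepoint}"


def _standardized_clr(proportions: np.ndarray) -> np.ndarray:
    # tiny Dirichlet concentrations can underflow to exact zeros
    z = clr(np.clip(proportions, 1e-9, None))
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (z - z.mean(axis=0)) / sd


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model described in the module docs."""
    rng = np.random.default_rng(config.seed)
    genera = [g for g, _p in config.genus_catalog]
    taxonomy = dict(config.genus_catalog)
    subjects = [f"S{i:04d}" for i in range(config.n_subjects)]
    n = config.n_subjects

    sex = rng.choice(["F", "M"], size=n)
    birthweight = rng.normal(config.birthweight_mean_g, config.birthweight_sd_g, n)
    bw_z = (birthweight - birthweight.mean()) / birthweight.std(ddof=0)
    u0 = rng.normal(0.0, config.subject_intercept_sd, n)

    # latent compositions + observed counts per stool time point
    taxon_tables: dict[str, TaxonTable] = {}
    clrz: dict[str, np.ndarray] = {}
    for tp in config.stool_timepoints:
        conc = np.asarray(config.composition_profiles[tp], float)
        props = rng.dirichlet(conc, size=n)
        libs = np.maximum(
            rng.lognormal(np.log(config.library_size), config.library_size_sigma, n),
            100,
        ).astype(int)
        counts = np.vstack([rng.multinomial(libs[i], props[i]) for i in range(n)])
        taxon_tables[tp] = TaxonTable(
            pd.DataFrame(
                counts,
                index=[f"{s}_{tp}" for s in subjects],
                columns=genera,
            ),
            taxonomy,
        )
        clrz[tp] = _standardized_clr(props)

    beta = np.array([config.effect_vector.get(g, 0.0) for g in genera])

    # zBMI forward recursion over anthropometry time points
    tps = list(config.anthro_timepoints)
    z = np.zeros((n, len(tps)))
    for t, tp in enumerate(tps):
        eps = rng.normal(0.0, config.noise_sd, n)
        val = u0 + config.birthweight_effect * bw_z + eps
        if t > 0:
            val += config.zbmi_ar * z[:, t - 1]
            prev = tps[t - 1]
            active = (
                config.effect_timepoints is None or prev in config.effect_timepoints
            )
            if prev in clrz and beta.any() and active:
                val += clrz[prev] @ beta
        z[:, t] = val

    # realise weight/length consistent with zBMI through the LMS reference
    reference = synthetic_reference()
    rows = []
    for t, tp in enumerate(tps):
        age = TIMEPOINT_AGE_DAYS.get(tp)
        if age is None:
            raise ValueError(f"no age mapping for time point {tp!r}")
        ages = age + rng.normal(0, max(1.0, 0.03 * age), n)
        ages = np.clip(ages, 1, 4700)
        years = ages / 365.25
        length = (
            50
            + 28 * (1 - np.exp(-years / 0.6))
            + 5.6 * years
            + rng.normal(0, 1.5, n)
        )
        for i, s in enumerate(subjects):
            L, M, S = reference.lms_at(sex[i], ages[i])
            bmi_val = inverse_lms(z[i, t], L, M, S)
            rows.append(
                {
                    "subject": s,
                    "time_point": tp,
                    "age_days": float(ages[i]),
                    "sex": sex[i],
                    "weight_kg": bmi_val * (length[i] / 100) ** 2,
                    "length_cm": float(length[i]),
                    "birthweight_g": float(birthweight[i]),
                    "zbmi": float(z[i, t]),
                }
            )
    cohort = pd.DataFrame(rows)

    truth = {
        "effect_vector": dict(zip(genera, beta)),
        "subject_intercepts": pd.Series(u0, index=subjects),
        "birthweight_z": pd.Series(bw_z, index=subjects),
        "clr_standardized": {
            tp: pd.DataFrame(clrz[tp], index=subjects, columns=genera)
            for tp in config.stool_timepoints
        },
        "zbmi_complete": cohort[["subject", "time_point", "zbmi"]].copy(),
        "config": config,
    }
    out = SyntheticCohort(cohort=cohort, taxon_tables=taxon_tables, truth=truth)
    if config.missing_rate_stool > 0 or config.missing_rate_anthro > 0:
        out = apply_missingness(
            out,
            rate_stool=config.missing_rate_stool,
            rate_anthro=config.missing_rate_anthro,
            mechanism=config.missing_mechanism,
            seed=rng.integers(2**31),
            mar_strength=config.mar_strength,
        )
    return out


def apply_missingness(
    cohort: SyntheticCohort,
    rate_stool: float = 0.0,
    rate_anthro: float = 0.0,
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_strength: float = 1.0,
) -> SyntheticCohort:
    """Mask anthropometry cells and drop stool samples, MCAR or MAR-on-zBMI.

    Under ``MAR-on-zBMI`` the masking probability increases with the
    subject's (complete-data) zBMI through a logistic link whose intercept
    is set so the marginal rate matches ``rate``; heavier children are thus
    likelier to have missing data, a realistic not-at-random-looking but
    still MAR pattern given zBMI is partly observed elsewhere.  Originals
    are retained in ``truth`` for imputation-quality checks.
    """
    for rate in (rate_stool, rate_anthro):
        if not 0 <= rate < 1:
            raise ValueError("rates must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR-on-zBMI"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    df = cohort.cohort.copy()

    def mask_prob(rate: float, z: np.ndarray) -> np.ndarray:
        if rate == 0:
            return np.zeros_like(z)
        if mechanism == "MCAR":
            return np.full_like(z, rate)
        return expit(logit(rate) + mar_strength * (z - z.mean()))

    if rate_anthro > 0:
        p = mask_prob(rate_anthro, df["zbmi"].to_numpy())
        masked = rng.random(len(df)) < p
        df.loc[masked, ["weight_kg", "length_cm", "zbmi"]] = np.nan

    tables = {}
    for tp, table in cohort.taxon_tables.items():
        sub = df[df["time_point"] == tp].set_index("subject")
        keep = np.ones(len(table.counts), dtype=bool)
        if rate_stool > 0:
            subj = [sid.rsplit("_", 1)[0] for sid in table.counts.index]
            z_tp = cohort.truth["zbmi_complete"]
            z_map = z_tp[z_tp["time_point"] == tp].set_index("subject")["zbmi"]
            zvals = np.array([z_map.get(s, 0.0) for s in subj])
            p = mask_prob(rate_stool, zvals)
            keep = rng.random(len(table.counts)) >= p
        tables[tp] = TaxonTable(table.counts.loc[keep].copy(), dict(table.taxonomy))

    truth = dict(cohort.truth)
    truth.setdefault("pre_missing_cohort", cohort.cohort.copy())
    return SyntheticCohort(cohort=df, taxon_tables=tables, truth=truth)
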