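"""End-to-end orchestration: features -> imputation -> confirmatory -> exploratory.

A single YAML config (or :class:`PipelineConfig`) names the inputs — per-time-
point genus count TSVs, a taxonomy map, a long anthropometry CSV, an LMS
growth-reference CSV and the SCFA-producer proxy TSV — plus per-stage
settings and one master seed from which every stage's stream is derived.
``run_pipeline`` writes, under the output directory:

    zbmi.csv               anthropometry with zBMI, outliers removed
    features.tsv           per-sample compositional features
    correlations.tsv       the two Spearman screening matrices
    posterior_summary.tsv  pooled multilevel posterior
    rf_report.tsv          RF accuracy/permutation family report
    rf_importances.tsv     per-feature importances for significant models
    manifest.json          config hash, seed, package versions, outputs
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import GrowthReference, flag_outliers, zbmi_table
from .compositions import (
    ProxyDefinition,
    TaxonTable,
    fb_ratio,
    observed_richness,
    relative_abundance,
    scfa_sum_score,
)
from .imputation import ImputationConfig, pmm_impute
from .multilevel import ModelSpec, fit_across_imputations, standardize
from .rf import run_model_family
from .screen import correlation_matrix
from .synthetic import ANTHRO_TIMEPOINTS, INFANT_TIMEPOINTS, STOOL_TIMEPOINTS

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "write_bundle"]


@dataclass
class PipelineConfig:
    anthro_csv: str = "anthro.csv"
    reference_csv: str = "reference.csv"
    taxonomy_tsv: str = "taxonomy.tsv"
    counts_tsv: dict[str, str] = field(default_factory=dict)  # tp -> path
    proxy_tsv: str | None = None
    out_dir: str = "out"
    seed: int = 0
    stool_timepoints: tuple[str, ...] = STOOL_TIMEPOINTS
    anthro_timepoints: tuple[str, ...] = ANTHRO_TIMEPOINTS
    exposure: str = "scfa_sum"  # or "fb_ratio"
    pseudocount: float = 0.5
    zbmi_bound: float = 3.0
    run_screen: bool = True
    run_multilevel: bool = True
    run_rf: bool = True
    imputation: dict = field(default_factory=lambda: {"m": 10, "iterations": 10, "donors": 5})
    multilevel: dict = field(default_factory=lambda: {"n_iter": 800, "n_chains": 2})
    rf: dict = field(
        default_factory=lambda: {
            "B": 199, "repeats": 10, "folds": 4, "tune_candidates": 20,
            "n_trees": 500, "retune": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["stool_timepoints"] = tuple(raw.get("stool_timepoints", STOOL_TIMEPOINTS))
        raw["anthro_timepoints"] = tuple(raw.get("anthro_timepoints", ANTHRO_TIMEPOINTS))
        return cls(**raw)


def lag_pairs(stool_tps, anthro_tps) -> list[tuple[str, str]]:
    """(stool tp, next anthropometry tp) exposure/outcome pairs."""
    order = list(anthro_tps)
    pairs = []
    for tp in stool_tps:
        if tp in order and order.index(tp) + 1 < len(order):
            pairs.append((tp, order[order.index(tp) + 1]))
    return pairs


def validate_inputs(
    anthro: pd.DataFrame,
    taxon_tables: dict[str, TaxonTable],
) -> list[str]:
    """Cross-reference and sanity checks; returns a list of violations."""
    issues = []
    subjects = set(anthro["subject"])
    for tp, table in taxon_tables.items():
        neg = np.argwhere(table.counts.to_numpy() < 0)
        for i, j in neg[:20]:
            issues.append(
                f"negative count: sample {table.counts.index[i]} genus "
                f"{table.counts.columns[j]}"
            )
        for sid in table.counts.index:
            if sid.rsplit("_", 1)[0] not in subjects:
                issues.append(f"sample {sid} ({tp}) has no subject in anthropometry")
    for subj, grp in anthro.dropna(subset=["age_days"]).groupby("subject"):
        order = [t for t in ANTHRO_TIMEPOINTS if t in set(grp["time_point"])]
        ages = grp.set_index("time_point").loc[order, "age_days"]
        if (ages.diff().dropna() <= 0).any():
            issues.append(f"subject {subj}: age not increasing across time points")
    bad_sex = set(anthro["sex"].dropna()) - {"F", "M", 1, 2, "1", "2", "female", "male"}
    if bad_sex:
        issues.append(f"unrecognised sex codes: {sorted(map(str, bad_sex))}")
    return issues


def _subject_index(table: TaxonTable) -> pd.Index:
    return pd.Index([sid.rsplit("_", 1)[0] for sid in table.counts.index])


def compute_features(
    taxon_tables: dict[str, TaxonTable],
    proxy: ProxyDefinition,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Long per-sample feature table: phylum proportions, F/B, SCFA score, richness."""
    frames = []
    for tp, table in taxon_tables.items():
        phylum = relative_abundance(table, level="phylum")
        for needed in ("Firmicutes", "Bacteroidetes"):
            if needed not in phylum.columns:
                phylum[needed] = 0.0
        df = pd.DataFrame(
            {
                "sample": table.counts.index,
                "subject": _subject_index(table),
                "time_point": tp,
                "firmicutes": phylum["Firmicutes"].to_numpy(),
                "bacteroidetes": phylum["Bacteroidetes"].to_numpy(),
                "fb_ratio": fb_ratio(phylum).to_numpy(),
                "scfa_sum": scfa_sum_score(table, proxy, pseudocount).to_numpy(),
                "richness": observed_richness(table).to_numpy(),
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _exposure_wide(features: pd.DataFrame, name: str) -> pd.DataFrame:
    return features.pivot(index="subject", columns="time_point", values=name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    s_imp, s_ml, s_rf = (int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(3))

    anthro = pd.read_csv(config.anthro_csv)
    reference = GrowthReference.from_csv(config.reference_csv)
    taxon_tables = {
        tp: TaxonTable.from_tsv(path, config.taxonomy_tsv)
        for tp, path in config.counts_tsv.items()
    }
    proxy = (
        ProxyDefinition.from_tsv(config.proxy_tsv)
        if config.proxy_tsv
        else ProxyDefinition()
    )

    issues = validate_inputs(anthro, taxon_tables)
    if issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))

    # anthropometry: (re)compute zBMI from raw measures, apply the outlier rule
    if "zbmi" not in anthro.columns or anthro["zbmi"].isna().all():
        anthro = zbmi_table(anthro, reference)
    else:
        anthro = zbmi_table(anthro.drop(columns=["zbmi"]), reference)
    kept, flagged = flag_outliers(anthro, bound=config.zbmi_bound)
    kept.to_csv(out / "zbmi.csv", index=False)

    features = compute_features(taxon_tables, proxy, config.pseudocount)
    features.to_csv(out / "features.tsv", sep="\t", index=False)

    zwide = kept.pivot(index="subject", columns="time_point", values="zbmi")
    zwide = zwide.reindex(columns=[t for t in config.anthro_timepoints if t in zwide])

    manifest_outputs = ["zbmi.csv", "features.tsv"]

    if config.run_screen:
        mats = []
        for name in ("fb_ratio", "scfa_sum"):
            expo = _exposure_wide(features, name).reindex(zwide.index)
            mats.append(
                correlation_matrix(expo, zwide, exposure_name=name)
            )
        pd.concat(mats, ignore_index=True).to_csv(
            out / "correlations.tsv", sep="\t", index=False
        )
        manifest_outputs.append("correlations.tsv")

    if config.run_multilevel:
        expo_name = config.exposure
        expo = _exposure_wide(features, expo_name).reindex(zwide.index)
        pairs = lag_pairs(config.stool_timepoints, config.anthro_timepoints)
        if expo_name == "fb_ratio":  # undefined for most infants: childhood only
            pairs = [p for p in pairs if p[0] not in INFANT_TIMEPOINTS]
        bw = kept.groupby("subject")["birthweight_g"].first().reindex(zwide.index)
        wide = pd.concat(
            [
                zwide.add_prefix("zbmi_"),
                expo.add_prefix("expo_"),
                bw.rename("birthweight_g"),
            ],
            axis=1,
        )
        icfg = ImputationConfig(seed=s_imp, **config.imputation)
        completed = pmm_impute(wide, icfg)

        def to_long(w: pd.DataFrame) -> pd.DataFrame:
            rows = []
            for prev, tp in pairs:
                sub = pd.DataFrame(
                    {
                        "subject": w.index,
                        "zbmi": w.get(f"zbmi_{tp}"),
                        "zbmi_lag": w.get(f"zbmi_{prev}"),
                        "exposure": w.get(f"expo_{prev}"),
                        "birthweight_g": w["birthweight_g"],
                    }
                )
                rows.append(sub)
            long = pd.concat(rows, ignore_index=True).dropna()
            long, _ = standardize(long, ["exposure", "birthweight_g"])
            return long

        spec = ModelSpec()
        summary, _draws = fit_across_imputations(
            [to_long(w) for w in completed],
            spec,
            n_iter=config.multilevel.get("n_iter", 800),
            n_chains=config.multilevel.get("n_chains", 2),
            seed=s_ml,
        )
        summary.to_csv(out / "posterior_summary.tsv", sep="\t")
        manifest_outputs.append("posterior_summary.tsv")

    if config.run_rf:
        report, importances, _ = run_model_family(
            taxon_tables,
            kept,
            config.anthro_timepoints,
            pseudocount=config.pseudocount,
            seed=s_rf,
            **config.rf,
        )
        report.to_csv(out / "rf_report.tsv", sep="\t", index=False)
        imp_frames = [
            res.table.assign(model=label) for label, res in importances.items()
        ]
        (
            pd.concat(imp_frames, ignore_index=True)
            if imp_frames
            else pd.DataFrame(columns=["feature", "importance", "p", "model"])
        ).to_csv(out / "rf_importances.tsv", sep="\t", index=False)
        manifest_outputs += ["rf_report.tsv", "rf_importances.tsv"]

    cfg_dict = asdict(config)
    manifest = {
        "package": "microgrowth",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_flagged_outliers": int(len(flagged)),
        "outputs": manifest_outputs + ["manifest.json"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_bundle(cohort, out_dir, reference=None) -> PipelineConfig:
    """Write a SyntheticCohort as the TSV/CSV bundle the pipeline reads."""
    from .anthropometry import synthetic_reference

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.cohort.to_csv(out / "anthro.csv", index=False)
    counts = {}
    first = True
    for tp, table in cohort.taxon_tables.items():
        path = out / f"counts_{tp}.tsv"
        table.to_tsv(path, out / "taxonomy.tsv" if first else None)
        counts[tp] = str(path)
        first = False
    (reference or synthetic_reference()).table.to_csv(out / "reference.csv", index=False)
    ProxyDefinition().to_tsv(out / "proxy.tsv")
    return PipelineConfig(
        anthro_csv=str(out / "anthro.csv"),
        reference_csv=str(out / "reference.csv"),
        taxonomy_tsv=str(out / "taxonomy.tsv"),
        counts_tsv=counts,
        proxy_tsv=str(out / "proxy.tsv"),
        out_dir=str(out / "report"),
    )
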