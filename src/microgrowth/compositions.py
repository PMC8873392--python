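"""Compositional microbiota features.

Genus-level 16S count tables are compositional: only relative information is
interpretable.  This module builds the features the downstream models
consume:

* relative abundances at genus or phylum level,
* the Firmicutes/Bacteroidetes (F/B) ratio, undefined when Bacteroidetes is
  absent (the division would be infinite, so the sample is excluded from
  ratio analyses rather than floored),
* the centred log-ratio (CLR) transform,
* an aggregated short-chain-fatty-acid (SCFA) producer score: raw counts of
  a curated list of SCFA-producing genera are summed into one feature which
  replaces its constituents, and the modified table is CLR-transformed,
* observed richness (number of genera present per sample).

Tables are pandas DataFrames with samples as rows and genera as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCFA_PRODUCERS",
    "ProxyDefinition",
    "TaxonTable",
    "CLRTransformer",
    "clr",
    "relative_abundance",
    "fb_ratio",
    "scfa_sum_score",
    "observed_richness",
    "abundance_filter",
]

# Curated SCFA-producer genera with phylum and main metabolite(s).
# Silva-style group names are kept verbatim.
DEFAULT_SCFA_PRODUCERS: tuple[tuple[str, str, str], ...] = (
    ("Bifidobacterium", "Actinobacteria", "acetate"),
    ("Alistipes", "Bacteroidetes", "propionate"),
    ("Bacteroides", "Bacteroidetes", "propionate"),
    ("Prevotella", "Bacteroidetes", "propionate"),
    ("Anaerostipes", "Firmicutes", "butyrate"),
    ("Blautia", "Firmicutes", "propionate"),
    ("Coprococcus", "Firmicutes", "propionate and butyrate"),
    ("Dialister", "Firmicutes", "propionate"),
    ("Eubacterium hallii group", "Firmicutes", "propionate and butyrate"),
    ("Eubacterium rectale group", "Firmicutes", "butyrate"),
    ("Faecalibacterium", "Firmicutes", "butyrate"),
    ("Holdemanella", "Firmicutes", "butyrate"),
    ("Phascolarctobacterium", "Firmicutes", "propionate"),
    ("Roseburia", "Firmicutes", "propionate and butyrate"),
    ("Subdoligranulum", "Firmicutes", "butyrate"),
    ("Desulfovibrio", "Proteobacteria", "acetate"),
    ("Akkermansia", "Verrucomicrobia", "propionate and acetate"),
)


def _norm_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class ProxyDefinition:
    """A curated list of (genus, SCFA produced) defining the proxy feature."""

    entries: tuple[tuple[str, str], ...] = tuple(
        (g, m) for g, _p, m in DEFAULT_SCFA_PRODUCERS
    )

    def __post_init__(self):
        if not self.entries:
            raise ValueError("proxy definition must be non-empty")
        names = [_norm_name(g) for g, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genus names in proxy definition")

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @classmethod
    def from_tsv(cls, path) -> "ProxyDefinition":
        df = pd.read_csv(path, sep="\t")
        g_col, m_col = df.columns[0], df.columns[1]
        return cls(tuple(zip(df[g_col].astype(str), df[m_col].astype(str))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["genus", "scfa"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class TaxonTable:
    """Samples x genera count table plus a genus -> phylum taxonomy map."""

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [g for g in self.counts.columns if g not in self.taxonomy]
        if missing:
            raise ValueError(f"genera missing from taxonomy map: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def genera(self) -> pd.Index:
        return self.counts.columns

    @classmethod
    def from_tsv(cls, counts_path, taxonomy_path) -> "TaxonTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        tax = pd.read_csv(taxonomy_path, sep="\t")
        taxonomy = dict(zip(tax.iloc[:, 0].astype(str), tax.iloc[:, 1].astype(str)))
        return cls(counts, taxonomy)

    def to_tsv(self, counts_path, taxonomy_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if taxonomy_path is not None:
            pd.DataFrame(
                sorted(self.taxonomy.items()), columns=["genus", "phylum"]
            ).to_csv(taxonomy_path, sep="\t", index=False)


def clr(x, pseudocount: float = 0.0) -> np.ndarray:
    """Centred log-ratio transform, natural log.

    ``clr(x)_i = log(x_i + pc) - mean_j log(x_j + pc)``.  Components of the
    result sum to zero.  A positive pseudocount is required whenever zeros
    are present.  Works on 1-D vectors or 2-D (samples x features) arrays,
    row-wise.
    """
    arr = np.asarray(x, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and (arr == 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    logged = np.log(arr + pseudocount)
    return logged - logged.mean(axis=-1, keepdims=True)


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the CLR row-wise.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Added to every entry before taking logs, so zero counts are
        representable.  Half a count is a common choice for integer count
        tables.
    """

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        return clr(X, self.pseudocount)


def relative_abundance(table: TaxonTable, level: str = "genus") -> pd.DataFrame:
    """Per-sample proportions at ``genus`` or ``phylum`` level (rows sum to 1)."""
    counts = table.counts
    if level == "phylum":
        counts = counts.T.groupby(
            lambda g: table.taxonomy[g]
        ).sum().T
    elif level != "genus":
        raise ValueError(f"unknown level {level!r}")
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return counts.div(totals, axis=0)


def fb_ratio(phylum_proportions: pd.DataFrame) -> pd.Series:
    """Firmicutes / Bacteroidetes ratio per sample.

    NaN where Bacteroidetes is 0 (the ratio would be infinite; such samples
    are excluded from ratio analyses, which in infant cohorts can be the
    majority).
    """
    for phylum in ("Firmicutes", "Bacteroidetes"):
        if phylum not in phylum_proportions.columns:
            raise KeyError(f"{phylum} column required")
    f = phylum_proportions["Firmicutes"]
    b = phylum_proportions["Bacteroidetes"]
    out = f / b.where(b > 0)
    out.name = "fb_ratio"
    return out


def scfa_sum_score(
    table: TaxonTable,
    proxy: ProxyDefinition | None = None,
    pseudocount: float = 0.5,
    return_table: bool = False,
):
    """Aggregated SCFA-producer score per sample.

    The raw counts of all proxy genera are summed into a single
    ``SCFA_sum`` feature replacing its constituents; the modified table
    (sum feature plus all non-proxy genera) is CLR-transformed and the
    ``SCFA_sum`` component returned.

    Proxy genera absent from the table raise an error when *none* overlap;
    a partial overlap proceeds with a logged warning (cohort tables rarely
    contain every curated genus).
    """
    if proxy is None:
        proxy = ProxyDefinition()
    norm_cols = {_norm_name(c): c for c in table.counts.columns}
    hits = [norm_cols[_norm_name(g)] for g in proxy.genera if _norm_name(g) in norm_cols]
    missing = [g for g in proxy.genera if _norm_name(g) not in norm_cols]
    if not hits:
        raise ValueError(f"no proxy genera found in table; missing: {missing}")
    if missing:
        logger.warning("proxy genera absent from table: %s", missing)
    others = [c for c in table.counts.columns if c not in hits]
    if not others:
        raise ValueError("table contains no non-proxy genera")
    modified = pd.concat(
        [table.counts[hits].sum(axis=1).rename("SCFA_sum"), table.counts[others]],
        axis=1,
    )
    transformed = pd.DataFrame(
        clr(modified.to_numpy(float), pseudocount),
        index=modified.index,
        columns=modified.columns,
    )
    score = transformed["SCFA_sum"]
    score.name = "scfa_sum_clr"
    if return_table:
        return score, transformed
    return score


def observed_richness(table: TaxonTable) -> pd.Series:
    """Number of genera with a nonzero count, per sample."""
    out = (table.counts > 0).sum(axis=1)
    out.name = "richness"
    return out


def abundance_filter(table: TaxonTable, min_rel_abundance: float = 0.001) -> TaxonTable:
    """Zero out per-sample counts below a relative-abundance threshold.

    Single pass: proportions are assessed against the *original* sample
    total, so surviving entries are not re-checked against the reduced
    total.  Threshold 0 is the identity.
    """
    if not 0 <= min_rel_abundance < 1:
        raise ValueError("threshold must be in [0, 1)")
    counts = table.counts.to_numpy(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    filtered = np.where(props < min_rel_abundance, 0, counts)
    return TaxonTable(
        pd.DataFrame(
            filtered.astype(table.counts.to_numpy().dtype),
            index=table.counts.index,
            columns=table.counts.columns,
        ),
        dict(table.taxonomy),
    )
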