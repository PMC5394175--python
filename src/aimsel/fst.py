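"""Per-SNP differentiation statistics and marker-set arithmetic.

Two per-locus fixation-index estimators over a sample grouping:

* ``weir_cockerham`` — the Weir & Cockerham (1984) variance-components
  estimator theta for one biallelic locus and k populations, with
  sample-size correction; values may be slightly negative and monomorphic
  loci are undefined.
* ``nei_gst`` — Nei's G_ST = (H_T - H_S)/H_T with unweighted population
  means; always in [0, 1], monomorphic loci are 0.

Quantile subsetting is threshold-based and ties-inclusive: *top 1%* means
every marker whose value reaches the empirical 99th-percentile threshold,
so the realized count can exceed ceil(0.01 N) when values tie at the cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ESTIMATORS = ("weir_cockerham", "nei_gst")


@dataclass
class Grouping:
    """A partition of samples into k >= 2 named groups."""

    name: str
    assignment: pd.Series  # index sample_id -> group label
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment)
        if not self.groups:
            self.groups = list(pd.unique(self.assignment))
        observed = set(self.assignment)
        if observed - set(self.groups):
            raise ValueError(f"labels outside declared groups: {observed - set(self.groups)}")
        counts = self.assignment.value_counts()
        empty = [g for g in self.groups if counts.get(g, 0) == 0]
        if empty:
            raise ValueError(f"empty groups: {empty}")
        if self.assignment.isna().any():
            raise ValueError("every sample must be assigned to a group")

    @classmethod
    def from_metadata(cls, samples: pd.DataFrame, column: str = "landrace", name: str | None = None) -> "Grouping":
        if column not in samples.columns or samples[column].isna().any():
            missing = samples.index[samples[column].isna()].tolist()[:5] if column in samples.columns else "all"
            raise ValueError(f"column '{column}' absent or missing for samples: {missing}")
        return cls(name or column, samples[column].astype(str))

    @property
    def k(self) -> int:
        return len(self.groups)

    def indices_for(self, sample_ids: pd.Index) -> dict[str, np.ndarray]:
        labels = self.assignment.reindex(sample_ids)
        if labels.isna().any():
            raise ValueError(
                f"samples without group assignment: {list(sample_ids[labels.isna()][:5])}"
            )
        return {g: np.flatnonzero((labels == g).to_numpy()) for g in self.groups}


@dataclass
class FstTable:
    """Per-marker F_ST values for one grouping; NaN marks undefined markers."""

    grouping: Grouping
    estimator: str
    values: pd.Series  # index marker_id
    sample_sizes: pd.DataFrame  # groups x markers: non-missing allele counts used

    @property
    def defined(self) -> pd.Series:
        return self.values.dropna()

    @property
    def n_undefined(self) -> int:
        return int(self.values.isna().sum())


@dataclass
class SnpSet:
    """A named set of marker ids with free-text provenance."""

    name: str
    members: set
    provenance: str = ""
    categories: dict | None = None

    def __len__(self) -> int:
        return len(self.members)


def _group_freqs(gm, grouping: Grouping):
    """Per-group sample sizes, allele-b frequencies and het fractions.

    Returns arrays of shape (k, n_markers): n (individuals with calls),
    p (allele-b frequency) and h (observed heterozygote fraction). Groups
    with zero non-missing calls at a marker yield NaN p/h there.
    """
    idx = grouping.indices_for(gm.sample_ids)
    k, m = grouping.k, gm.n_snps
    n = np.zeros((k, m))
    p = np.full((k, m), np.nan)
    h = np.full((k, m), np.nan)
    for gi, g in enumerate(grouping.groups):
        block = gm.calls[idx[g]]
        called = np.isfinite(block)
        cnt = called.sum(axis=0)
        n[gi] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[gi] = np.nansum(block, axis=0) / (2 * cnt)
            h[gi] = np.nansum(block == 1, axis=0) / cnt
    return n, p, h


def weir_cockerham_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Vectorized Weir-Cockerham (1984) theta for biallelic loci.

    ``n``/``p``/``h`` are (k, m) arrays of per-population sample sizes
    (diploid individuals), allele frequencies and heterozygote fractions.
    Returns an array of length m; NaN where the estimator is undefined
    (monomorphic locus, a population with no data, or n_bar <= 1).
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    theta = np.where((n == 0).any(axis=0) | (n_bar <= 1) | (n_c <= 0), np.nan, theta)
    return theta


def nei_gst(p: np.ndarray) -> np.ndarray:
    """Nei's G_ST from per-population allele frequencies (unweighted means)."""
    p_bar = np.nanmean(p, axis=0)
    ht = 2 * p_bar * (1 - p_bar)
    hs = np.nanmean(2 * p * (1 - p), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = np.where(ht > 0, 1 - hs / ht, 0.0)
    gst = np.where(np.isnan(p).any(axis=0), np.nan, gst)
    return np.clip(gst, 0.0, 1.0)


def fst_per_snp(gm, grouping: Grouping, estimator: str = "weir_cockerham") -> FstTable:
    """One F_ST value per marker from observed per-group allele frequencies.

    Missing calls are dropped per marker per group. Markers where a group has
    zero non-missing calls are flagged NaN and excluded from downstream
    quantile subsetting; monomorphic markers are 0 under ``nei_gst`` and NaN
    (undefined) under ``weir_cockerham``.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if grouping.k < 2:
        raise ValueError("need at least 2 groups")
    n, p, h = _group_freqs(gm, grouping)
    if estimator == "weir_cockerham":
        vals = weir_cockerham_theta(n, p, h)
    else:
        vals = nei_gst(p)
    values = pd.Series(vals, index=gm.marker_ids, name="fst")
    sizes = pd.DataFrame(2 * n, index=pd.Index(grouping.groups, name="group"), columns=gm.marker_ids)
    return FstTable(grouping, estimator, values, sizes)


def summarize_fst(tbl: FstTable) -> dict:
    """min/max/mean/sd/count over the defined values."""
    vals = tbl.defined
    if vals.empty:
        raise ValueError("no defined F_ST values to summarize")
    out = {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "count": int(len(vals)),
    }
    if len(vals) == 1:
        out["note"] = "single defined value; sd reported as 0"
    return out


def top_quantile(tbl: FstTable, q: float) -> SnpSet:
    """Markers in the upper ``q`` tail of the F_ST distribution, ties included.

    The threshold is the empirical (1-q) quantile of the defined values;
    every marker with value >= threshold is a member, so the realized count
    can exceed ceil(q*N) under ties.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    vals = tbl.defined
    if len(vals) < 1 / q:
        warnings.warn(
            f"only {len(vals)} defined markers for q={q}; returning the upper tail of those",
            stacklevel=2,
        )
    thr = float(np.quantile(vals.to_numpy(), 1 - q))
    members = set(vals.index[vals.to_numpy() >= thr])
    prov = (
        f"top_quantile(q={q}) on {tbl.estimator} F_ST over grouping '{tbl.grouping.name}': "
        f"threshold={thr:.6g}, count={len(members)}, undefined_excluded={tbl.n_undefined}"
    )
    return SnpSet(name=f"high_fst_q{q}", members=members, provenance=prov)


def load_marker_list(path) -> SnpSet:
    """Read a newline-delimited marker list with an optional category column."""
    members: list[str] = []
    categories: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            members.append(tok[0])
            if len(tok) > 1:
                categories[tok[0]] = tok[1]
    if not members:
        raise ValueError(f"{path}: empty marker list")
    unique = set(members)
    if len(unique) < len(members):
        warnings.warn(f"{path}: {len(members) - len(unique)} duplicate marker ids removed", stacklevel=2)
    return SnpSet(
        name=str(path),
        members=unique,
        provenance=f"loaded from {path}",
        categories=categories or None,
    )


def set_relations(a: SnpSet, b: SnpSet) -> dict:
    """Exact set arithmetic between two marker sets."""
    inter = a.members & b.members
    return {
        "a": len(a.members),
        "b": len(b.members),
        "intersection": len(inter),
        "a_only": len(a.members - b.members),
        "b_only": len(b.members - a.members),
        "shared_members": sorted(inter),
    }
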