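"""Parameter-recovery benchmark on the default synthetic cohort.

The benchmark plants a known marker-class structure (truth table) with the
generator, runs the full landrace and altitude analyses, and measures how
well the method recovers it:

* the cluster-number contrast — the BIC scan on *all* markers versus on the
  high-F_ST subset (real panels show structure only in the subset);
* recall of the planted landrace- and altitude-class loci in the respective
  informative panels;
* hypergeometric enrichment of the shared output panel for planted
  shared-class loci;
* self-assignment accuracy of the landrace DAPC.

Recovery is evaluated as recall at an oracle-sized panel: the subsetting
quantile is q = 0.05 (the planted share of the cohort) and the informative
rule is top_count(m) with m equal to the number of planted loci of the
evaluated class, on eigenvalue-weighted combined contributions. This probes
whether the method *ranks* the planted loci at the top; the user-facing
pipeline defaults stay at the chip-study dialect (q = 0.01, top 2% per
function).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dapc import DAPC, TopCount, select_informative
from .decompose import kmeans_bic_scan, run_pca
from .fst import Grouping, SnpSet, fst_per_snp, summarize_fst, top_quantile
from .pipeline import compare_informative, dichotomize_altitude, enrichment_pvalue
from .simulate import SimConfig, simulate

BENCH_Q = 0.05
BENCH_N_PCA = 10


@dataclass
class BenchmarkResult:
    """Quantities measured on one synthetic cohort."""

    n_samples: int
    n_markers: int
    mean_background_fst: float
    mean_landrace_fst: float
    best_k_all: int
    best_k_high_fst: int
    landrace_recall_percent: float
    altitude_recall_percent: float
    shared_enrichment_p: float
    landrace_accuracy_percent: float
    altitude_accuracy_percent: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _informative_panel(gm, grouping: Grouping, members: set, m: int, n_pca: int):
    sub = gm.take_snps(gm.marker_ids[gm.marker_ids.isin(members)])
    n_pca = min(n_pca, sub.n_samples - 1, sub.n_snps)
    res = DAPC(sub, grouping, n_pca=n_pca, n_disc=min(grouping.k - 1, n_pca)).fit()
    panel = select_informative(res.contributions(None), TopCount(m))
    return panel, res


def run_benchmark(seed: int, config: SimConfig | None = None) -> BenchmarkResult:
    """Simulate the default cohort at ``seed`` and measure recovery."""
    config = config or SimConfig(seed=int(seed) % (2**31))
    gm, truth = simulate(config)
    classes = truth["class"]

    landrace_grouping = Grouping.from_metadata(gm.samples, "landrace")
    tbl = fst_per_snp(gm, landrace_grouping)
    background = set(classes.index[classes == "background"])
    planted_landrace = set(classes.index[classes.isin(["landrace", "shared"])])
    planted_altitude = set(classes.index[classes.isin(["altitude", "shared"])])
    planted_shared = set(classes.index[classes == "shared"])
    mean_bg = float(tbl.values.reindex(sorted(background)).mean())
    mean_lr = float(tbl.values.reindex(sorted(planted_landrace)).mean())

    # cluster-number contrast: all markers vs the high-F_ST subset
    scan_all = kmeans_bic_scan(run_pca(gm), k_min=1, k_max=5, seed=config.seed)
    top1 = top_quantile(tbl, 0.01)
    sub1 = gm.take_snps(gm.marker_ids[gm.marker_ids.isin(top1.members)])
    scan_high = kmeans_bic_scan(run_pca(sub1), k_min=1, k_max=5, seed=config.seed)

    # landrace recovery at oracle panel size
    high_lr = top_quantile(tbl, BENCH_Q)
    lr_panel, lr_res = _informative_panel(
        gm, landrace_grouping, high_lr.members, m=len(planted_landrace), n_pca=BENCH_N_PCA
    )
    lr_recall = 100.0 * len(lr_panel.members & planted_landrace) / len(planted_landrace)

    # altitude recovery
    altitude_grouping = dichotomize_altitude(gm.samples)
    tbl_alt = fst_per_snp(gm, altitude_grouping)
    high_alt = top_quantile(tbl_alt, BENCH_Q)
    alt_panel, alt_res = _informative_panel(
        gm, altitude_grouping, high_alt.members, m=len(planted_altitude), n_pca=BENCH_N_PCA
    )
    alt_recall = 100.0 * len(alt_panel.members & planted_altitude) / len(planted_altitude)

    report = compare_informative(lr_panel, alt_panel)
    p_shared = enrichment_pvalue(gm.n_snps, planted_shared, report.shared.members)

    return BenchmarkResult(
        n_samples=gm.n_samples,
        n_markers=gm.n_snps,
        mean_background_fst=mean_bg,
        mean_landrace_fst=mean_lr,
        best_k_all=scan_all.best_k,
        best_k_high_fst=scan_high.best_k,
        landrace_recall_percent=lr_recall,
        altitude_recall_percent=alt_recall,
        shared_enrichment_p=p_shared,
        landrace_accuracy_percent=lr_res.accuracy(),
        altitude_accuracy_percent=alt_res.accuracy(),
    )
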