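"""End-to-end landrace and altitude analyses and their comparison.

Each analysis runs the same chain over a different sample grouping:
per-SNP F_ST -> upper-quantile subsetting -> k-means/BIC cluster scans on
{all markers, optional named list, high-F_ST subset} -> DAPC on the
high-F_ST subset -> per-marker contributions -> informative-marker
selection. The confound report then partitions the landrace- and
altitude-informative panels into shared and analysis-specific markers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dapc import DAPC, DAPCResults, MeanPlusSd, MembershipTable, TopCount, TopFraction, select_informative
from .decompose import ClusterScan, kmeans_bic_scan, run_pca
from .fst import FstTable, Grouping, SnpSet, fst_per_snp, summarize_fst, top_quantile
from .genotypes import ConfigurationError, GenotypeMatrix

logger = logging.getLogger("aimsel")

RULES = {"top_fraction": TopFraction, "top_count": TopCount, "mean_plus_sd": MeanPlusSd}


@dataclass
class AnalysisConfig:
    """Flat configuration for one analysis run.

    ``informative_rule`` is ``(name, value)`` with name in {top_fraction,
    top_count, mean_plus_sd}; per-function selections are unioned.
    """

    estimator: str = "weir_cockerham"
    q: float = 0.01
    k_min: int = 1
    k_max: int = 5
    n_pcs_scan: int | None = None
    n_pca: int = 4
    n_disc: int = 2
    informative_rule: tuple[str, float] = ("top_fraction", 0.02)
    altitude_threshold: float = 750.0
    scale: bool = False
    n_starts: int = 10
    seed: int = 0

    def rule(self):
        name, value = self.informative_rule
        if name not in RULES:
            raise ConfigurationError(f"unknown informative rule '{name}'")
        return RULES[name](int(value) if name == "top_count" else float(value))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["informative_rule"] = list(d["informative_rule"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "informative_rule" in d:
            name, value = d["informative_rule"]
            d["informative_rule"] = (name, value)
        return cls(**d)


def default_altitude_config(**overrides) -> AnalysisConfig:
    """Altitude-analysis defaults: one PC, one discriminant function."""
    base = dict(n_pca=1, n_disc=1)
    base.update(overrides)
    return AnalysisConfig(**base)


@dataclass
class AnalysisBundle:
    """Everything one analysis produced, in pipeline order."""

    grouping: Grouping
    fst: FstTable
    fst_summary: dict
    high_set: SnpSet
    scans: dict[str, ClusterScan]
    dapc: DAPCResults
    membership: MembershipTable
    accuracy: float
    per_function_sets: dict[int, SnpSet]
    informative: SnpSet


@dataclass
class ConfoundReport:
    """SNP-level partition of the two informative panels."""

    landrace_informative: SnpSet
    altitude_informative: SnpSet
    shared: SnpSet
    landrace_only: SnpSet
    altitude_only: SnpSet
    gene_level_notes: str = ""

    def counts(self) -> dict:
        return {
            "landrace_informative": len(self.landrace_informative),
            "altitude_informative": len(self.altitude_informative),
            "shared": len(self.shared),
            "landrace_only": len(self.landrace_only),
            "altitude_only": len(self.altitude_only),
        }


def dichotomize_altitude(samples: pd.DataFrame, threshold: float = 750.0) -> Grouping:
    """Split samples into low (altitude <= threshold masl) and high groups."""
    if "altitude_masl" not in samples.columns or samples["altitude_masl"].isna().any():
        missing = (
            samples.index[samples["altitude_masl"].isna()].tolist()
            if "altitude_masl" in samples.columns
            else list(samples.index)
        )
        raise ConfigurationError(f"altitude missing for samples: {missing[:10]}")
    labels = np.where(samples["altitude_masl"] <= threshold, "low", "high")
    present = [g for g in ("low", "high") if g in labels]
    return Grouping("altitude", pd.Series(labels, index=samples.index), groups=present)


def _run_analysis(
    gm: GenotypeMatrix,
    grouping: Grouping,
    config: AnalysisConfig,
    marker_list: SnpSet | None = None,
) -> AnalysisBundle:
    stage = "fst"
    try:
        tbl = fst_per_snp(gm, grouping, estimator=config.estimator)
        summary = summarize_fst(tbl)
        logger.info(
            "[%s] F_ST (%s): %d markers, mean=%.4f max=%.4f",
            grouping.name, config.estimator, summary["count"], summary["mean"], summary["max"],
        )
        stage = "top_quantile"
        high = top_quantile(tbl, config.q)
        logger.info("[%s] high-F_ST subset: %s", grouping.name, high.provenance)

        stage = "cluster_scans"
        scans: dict[str, ClusterScan] = {}
        scan_sets = {"all": None, "high_fst": high}
        if marker_list is not None:
            scan_sets["list"] = marker_list
        for name, snp_set in scan_sets.items():
            sub = gm if snp_set is None else gm.take_snps(
                gm.marker_ids[gm.marker_ids.isin(snp_set.members)]
            )
            pca = run_pca(sub, scale=config.scale)
            scans[name] = kmeans_bic_scan(
                pca,
                k_min=config.k_min,
                k_max=min(config.k_max, sub.n_samples),
                n_pcs=config.n_pcs_scan,
                seed=config.seed,
                n_starts=config.n_starts,
            )
            logger.info(
                "[%s] BIC scan on '%s' (%d markers, %d PCs): best k = %d",
                grouping.name, name, sub.n_snps, scans[name].n_pcs_used, scans[name].best_k,
            )

        stage = "dapc"
        sub = gm.take_snps(gm.marker_ids[gm.marker_ids.isin(high.members)])
        res = DAPC(sub, grouping, n_pca=config.n_pca, n_disc=config.n_disc, scale=config.scale).fit()
        membership = res.predict()
        acc = res.accuracy()
        logger.info("[%s] DAPC n_pca=%d n_disc=%d self-assignment=%.1f%%",
                    grouping.name, res.n_pca, res.n_disc, acc)

        stage = "select_informative"
        rule = config.rule()
        per_function: dict[int, SnpSet] = {}
        union: set = set()
        for f in range(1, res.n_disc + 1):
            sel = select_informative(res.contributions(f), rule)
            per_function[f] = sel
            union |= sel.members
        informative = SnpSet(
            name=f"{grouping.name}_informative",
            members=union,
            provenance=f"union over {res.n_disc} function(s) of {rule}",
        )
        logger.info("[%s] informative panel: %d markers", grouping.name, len(informative))
    except Exception as exc:
        raise RuntimeError(f"{grouping.name} analysis failed at stage '{stage}': {exc}") from exc
    return AnalysisBundle(
        grouping=grouping,
        fst=tbl,
        fst_summary=summary,
        high_set=high,
        scans=scans,
        dapc=res,
        membership=membership,
        accuracy=acc,
        per_function_sets=per_function,
        informative=informative,
    )


def run_landrace_analysis(
    gm: GenotypeMatrix, config: AnalysisConfig | None = None, marker_list: SnpSet | None = None
) -> AnalysisBundle:
    """F_ST by landrace, subsetting, cluster scans, DAPC and panel selection."""
    config = config or AnalysisConfig()
    grouping = Grouping.from_metadata(gm.samples, "landrace")
    return _run_analysis(gm, grouping, config, marker_list=marker_list)


def run_altitude_analysis(
    gm: GenotypeMatrix, config: AnalysisConfig | None = None, marker_list: SnpSet | None = None
) -> AnalysisBundle:
    """The same chain with samples dichotomized at the altitude threshold."""
    config = config or default_altitude_config()
    grouping = dichotomize_altitude(gm.samples, config.altitude_threshold)
    return _run_analysis(gm, grouping, config, marker_list=marker_list)


def compare_informative(landrace: SnpSet, altitude: SnpSet, notes: str = "") -> ConfoundReport:
    """Partition the two panels into shared / landrace-only / altitude-only."""
    shared = landrace.members & altitude.members
    return ConfoundReport(
        landrace_informative=landrace,
        altitude_informative=altitude,
        shared=SnpSet("shared", shared, "intersection of the two panels"),
        landrace_only=SnpSet("landrace_only", landrace.members - shared, "landrace \\ altitude"),
        altitude_only=SnpSet("altitude_only", altitude.members - shared, "altitude \\ landrace"),
        gene_level_notes=notes,
    )


def enrichment_pvalue(n_universe: int, class_members: set, selected: set) -> float:
    """Hypergeometric upper-tail P of the observed class/selection overlap.

    P(X >= overlap) when ``len(selected)`` draws are made without replacement
    from a universe of ``n_universe`` markers containing ``len(class_members)``
    successes.
    """
    overlap = len(class_members & selected)
    return float(hypergeom.sf(overlap - 1, n_universe, len(class_members), len(selected)))


# ---------------------------------------------------------------------------
# Full run + report
# ---------------------------------------------------------------------------

def run_full(
    gm: GenotypeMatrix,
    landrace_config: AnalysisConfig | None = None,
    altitude_config: AnalysisConfig | None = None,
    marker_list: SnpSet | None = None,
    notes: str = "",
) -> dict:
    """Both analyses plus the comparison; returns bundles and the report."""
    landrace = run_landrace_analysis(gm, landrace_config, marker_list=marker_list)
    altitude = run_altitude_analysis(gm, altitude_config, marker_list=marker_list)
    report = compare_informative(landrace.informative, altitude.informative, notes=notes)
    return {"landrace": landrace, "altitude": altitude, "compare": report}


def write_bundle(bundle: AnalysisBundle, out_dir, prefix: str) -> None:
    """TSV/JSON exports for one analysis (deterministic ordering)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fst_df = pd.DataFrame(
        {
            "marker_id": bundle.fst.values.index,
            "fst": bundle.fst.values.to_numpy(),
        }
    )
    fst_df.to_csv(out_dir / f"{prefix}.fst.tsv", sep="\t", index=False)
    for name, scan in bundle.scans.items():
        scan.to_frame().to_csv(out_dir / f"{prefix}.scan_{name}.tsv", sep="\t", index=False)
    bundle.membership.posteriors.rename_axis("sample_id").reset_index().to_csv(
        out_dir / f"{prefix}.membership.tsv", sep="\t", index=False
    )
    rows = []
    for f, sel in bundle.per_function_sets.items():
        contrib = bundle.dapc.contributions(f).contributions
        for mid in contrib.index:
            rows.append((mid, f, contrib[mid], mid in sel.members))
    pd.DataFrame(rows, columns=["marker_id", "function", "contribution", "selected"]).to_csv(
        out_dir / f"{prefix}.contributions.tsv", sep="\t", index=False
    )
    with open(out_dir / f"{prefix}.summary.json", "w") as fh:
        json.dump(
            {
                "fst_summary": bundle.fst_summary,
                "high_fst": {"count": len(bundle.high_set), "provenance": bundle.high_set.provenance},
                "best_k": {name: scan.best_k for name, scan in bundle.scans.items()},
                "dapc": {
                    "n_pca": bundle.dapc.n_pca,
                    "n_disc": bundle.dapc.n_disc,
                    "eigenvalues": [float(v) for v in bundle.dapc.eigenvalues],
                    "self_assignment_percent": bundle.accuracy,
                },
                "informative": {
                    "count": len(bundle.informative),
                    "members": sorted(bundle.informative.members),
                    "provenance": bundle.informative.provenance,
                },
            },
            fh,
            indent=2,
        )
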