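"""Balding-Nichols synthetic genotypes with planted marker classes.

The generator emulates the structure of a small landrace diversity panel
genotyped on a dense SNP chip: five groups of 8-14 accessions, a large
background of weakly differentiated loci, a small tail of strongly
differentiated (landrace-selected) loci, altitude-clinal loci, loci carrying
both signals, locus-level admixture between selected group pairs, one
near-isolated group, and missing calls.

Model
-----
Each locus draws an ancestral allele frequency p ~ Uniform(0.05, 0.95). Each
group's frequency follows the Balding-Nichols distribution

    p_g ~ Beta(p (1-F)/F, (1-p)(1-F)/F)

whose dispersion parameter F equals the expected F_ST of the locus class —
so recovery targets are analytic. Altitude-clinal loci shift each sample's
frequency on the logit scale, logit(p_s) = logit(p_g) + slope * (alt_km - 1),
centred at 1 km so the ancestral frequency is roughly unbiased over the
panel. Diploid dosages are Binomial(2, p_s); a missing mask is applied
uniformly at random. The truth table records each marker's planted class
(background / landrace / altitude / shared) for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotypes import GenotypeMatrix, write_outputs

LANDRACE_NAMES = ["ZapaloteChico", "ZapaloteGrande", "Conejo", "Tehua", "Comiteco"]

# Per-group altitude bands (masl). The first group is entirely low-altitude
# (like Zapalote Chico, 5-700 masl); the others overlap the 750 masl cut to
# reproduce the landrace/altitude confounding of real panels.
DEFAULT_ALTITUDE_BANDS = [(5, 700), (100, 1100), (300, 1500), (700, 2300), (900, 2500)]

MARKER_CLASSES = ("background", "landrace", "altitude", "shared")

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort; the defaults emulate a 50-sample,
    five-landrace chip panel with a ~5% planted tail over a 0.056-mean
    background."""

    n_groups: int = 5
    samples_per_group: list[int] = field(default_factory=lambda: [12, 8, 9, 11, 10])
    n_background: int = 2000
    fst_background: float = 0.056
    n_landrace_loci: int = 40
    fst_landrace: float = 0.4
    n_altitude_loci: int = 40
    altitude_effect: float = 2.0  # logit-scale slope per km of altitude
    n_shared_loci: int = 20
    admixture_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(3, 4, 0.20), (1, 2, 0.10)]
    )
    isolated_group: int | None = 0
    isolated_drift: float = 1.5  # multiplier on F for the isolated group
    altitude_bands: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_ALTITUDE_BANDS)
    )
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.samples_per_group) != self.n_groups:
            raise ValueError("samples_per_group must have n_groups entries")
        if any(s < 1 for s in self.samples_per_group):
            raise ValueError("each group needs at least one sample")
        for name, f in (("fst_background", self.fst_background), ("fst_landrace", self.fst_landrace)):
            if not 0 < f < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_background, self.n_landrace_loci, self.n_altitude_loci, self.n_shared_loci) < 0:
            raise ValueError("locus counts must be >= 0")
        if len(self.altitude_bands) < self.n_groups:
            raise ValueError("need an altitude band per group")
        if self.isolated_group is not None and not 0 <= self.isolated_group < self.n_groups:
            raise ValueError("isolated_group out of range")
        for g1, g2, w in self.admixture_pairs:
            if not (0 <= g1 < self.n_groups and 0 <= g2 < self.n_groups) or not 0 <= w < 1:
                raise ValueError(f"bad admixture pair ({g1}, {g2}, {w})")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_group)

    @property
    def n_markers(self) -> int:
        return self.n_background + self.n_landrace_loci + self.n_altitude_loci + self.n_shared_loci


def _balding_nichols(rng, p_anc: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Draw one group's frequencies around ancestral p with dispersion F."""
    f = np.clip(f, 0.0, 0.95)
    out = p_anc.copy()
    drift = f > 1e-9
    if drift.any():
        a = p_anc[drift] * (1 - f[drift]) / f[drift]
        b = (1 - p_anc[drift]) * (1 - f[drift]) / f[drift]
        out[drift] = rng.beta(a, b)
    return out


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a genotype matrix and its truth table from ``config``.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The cohort, and a truth table indexed by marker_id with a ``class``
        column partitioning markers into background / landrace / altitude /
        shared.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    m = config.n_markers
    k = config.n_groups

    classes = np.array(
        ["background"] * config.n_background
        + ["landrace"] * config.n_landrace_loci
        + ["altitude"] * config.n_altitude_loci
        + ["shared"] * config.n_shared_loci
    )
    # Group-level drift F per locus: landrace and shared loci drift hard,
    # background and altitude loci drift at the genomic background rate
    # (the altitude signal is the per-sample cline, not group drift).
    f_locus = np.where(
        np.isin(classes, ("landrace", "shared")), config.fst_landrace, config.fst_background
    )

    p_anc = rng.uniform(0.05, 0.95, size=m)
    group_freq = np.empty((k, m))
    for g in range(k):
        f_g = f_locus.copy()
        if config.isolated_group is not None and g == config.isolated_group:
            f_g = f_g * config.isolated_drift
        group_freq[g] = _balding_nichols(rng, p_anc, f_g)

    # sample registry
    group_of = np.repeat(np.arange(k), config.samples_per_group)
    altitude = np.empty(n)
    for g in range(k):
        lo, hi = config.altitude_bands[g]
        rows = group_of == g
        altitude[rows] = rng.uniform(lo, hi, size=rows.sum())
    if k <= len(LANDRACE_NAMES):
        names = LANDRACE_NAMES[:k]
    else:
        names = [f"group{g}" for g in range(k)]
    sample_ids = [f"{names[g]}_{i+1:02d}" for g in range(k) for i in range(config.samples_per_group[g])]

    # per-sample locus frequencies
    freq = group_freq[group_of]  # n x m
    admix_source = {}
    for g1, g2, w in config.admixture_pairs:
        admix_source.setdefault(g1, []).append((g2, w))
    for g1, partners in admix_source.items():
        rows = np.flatnonzero(group_of == g1)
        for g2, w in partners:
            mask = rng.random((len(rows), m)) < w
            freq[rows] = np.where(mask, group_freq[g2][None, :], freq[rows])

    clinal = np.isin(classes, ("altitude", "shared"))
    if clinal.any():
        alt_km = altitude / 1000.0
        base = np.clip(freq[:, clinal], 1e-6, 1 - 1e-6)
        shift = config.altitude_effect * (alt_km - 1.0)[:, None]
        freq[:, clinal] = expit(logit(base) + shift)
    freq = np.clip(freq, 1e-6, 1 - 1e-6)

    calls = rng.binomial(2, freq).astype(float)
    if config.missing_rate > 0:
        calls[rng.random((n, m)) < config.missing_rate] = np.nan

    width = len(str(m))
    marker_ids = [f"snp{j+1:0{width}d}" for j in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    snps = pd.DataFrame(
        {
            "chromosome": [str(1 + j % 10) for j in range(m)],
            "position": [1000 + 100 * (j // 10) for j in range(m)],
            "allele_a": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "allele_b": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "gentrain_score": np.round(rng.uniform(0.4, 1.0, size=m), 4),
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    samples = pd.DataFrame(
        {
            "landrace": [names[g] for g in group_of],
            "altitude_masl": np.round(altitude, 1),
            "latitude": np.round(rng.uniform(15.0, 18.5, size=n), 4),
            "longitude": np.round(rng.uniform(-97.5, -91.0, size=n), 4),
            "collection_year": rng.integers(1946, 2011, size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gm = GenotypeMatrix(calls, samples, snps)
    truth = pd.DataFrame({"class": classes}, index=snps.index)
    return gm, truth


PROFILES = {
    "tiny": dict(
        samples_per_group=[4, 4, 4, 4, 4],
        n_background=440,
        n_landrace_loci=24,
        n_altitude_loci=24,
        n_shared_loci=12,
    ),
    "default": dict(),
    "paper_scale": dict(
        n_background=35_809,
        n_landrace_loci=40,
        n_altitude_loci=40,
        n_shared_loci=20,
    ),
}


def make_fixture(profile_name: str, out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a named simulation profile (PED/MAP, metadata TSVs, truth TSV).

    ``tiny`` is a 20-sample x 500-marker cohort for unit tests; ``default``
    the 50 x 2,100 benchmark cohort; ``paper_scale`` a 50-sample x 35,909-
    marker cohort at chip scale. Identical seeds give byte-identical files.
    """
    if profile_name not in PROFILES:
        raise ValueError(f"unknown profile '{profile_name}'; choose from {sorted(PROFILES)}")
    config = SimConfig(seed=seed, **PROFILES[profile_name])
    gm, truth = simulate(config)
    out_dir = Path(out_dir)
    paths = write_outputs(gm, out_dir, prefix=profile_name)
    truth_path = out_dir / f"{profile_name}.truth.tsv"
    truth.rename_axis("marker_id").reset_index().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
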