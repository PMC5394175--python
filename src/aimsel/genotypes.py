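"""Genotype matrices and PLINK-text I/O.

The central container is :class:`GenotypeMatrix`: a samples x SNPs array of
diploid allele-dosage calls (0/1/2, NaN for missing) counting copies of
``allele_b``, together with a sample registry (landrace label, altitude and
collection metadata) and a marker registry (chromosome, position, allele pair,
optional Illumina GenTrain score).

Coding convention: for a biallelic marker ``allele_b`` is the lexicographically
larger of the two observed alleles, so the same marker read from two files gets
the same dosage orientation and datasets can be merged without a reference
panel. A monomorphic marker stores its single observed allele as ``allele_a``
with ``allele_b = '0'`` (dosage 0 everywhere); an entirely missing marker is
stored as ``('N', '0')``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_ALLELE = "0"

SAMPLE_COLUMNS = ["landrace", "altitude_masl", "latitude", "longitude", "collection_year"]
SNP_COLUMNS = ["chromosome", "position", "allele_a", "allele_b", "gentrain_score"]


class PlinkFormatError(ValueError):
    """Malformed PED/MAP input (ragged rows, dimension mismatch, >2 alleles)."""


class ConfigurationError(ValueError):
    """A filter or analysis was requested without the metadata it needs."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls with sample and marker registries.

    Parameters
    ----------
    calls : ndarray, shape (n_samples, n_snps)
        Allele-dosage calls in {0, 1, 2} counting copies of ``allele_b``;
        missing calls are NaN.
    samples : DataFrame indexed by unique sample_id
        Columns (all optional): landrace, altitude_masl, latitude, longitude,
        collection_year.
    snps : DataFrame indexed by unique marker_id
        Columns: chromosome, position (1-based bp), allele_a, allele_b and
        optionally gentrain_score in [0, 1].
    """

    calls: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x SNPs array")
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.snps) != m:
            raise ValueError(
                f"registry sizes ({len(self.samples)} samples, {len(self.snps)} SNPs) "
                f"do not match calls shape {self.calls.shape}"
            )
        if not self.samples.index.is_unique:
            raise ValueError("sample_id values must be unique")
        if not self.snps.index.is_unique:
            raise ValueError("marker_id values must be unique")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing calls must be 0, 1 or 2")
        if m:
            pos = self.snps["position"]
            if (pos < 1).any():
                raise ValueError("marker positions must be >= 1 (1-based)")
            a = self.snps["allele_a"].astype(str)
            b = self.snps["allele_b"].astype(str)
            if (a == b).any():
                raise ValueError("allele_a must differ from allele_b")
            biallelic = b != MISSING_ALLELE
            if (a[biallelic] > b[biallelic]).any():
                bad = self.snps.index[biallelic & (a > b)][:5].tolist()
                raise ValueError(
                    f"biallelic markers must be coded with allele_a < allele_b: {bad}"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.snps.index

    def missing_fraction_per_snp(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=1)

    def take_samples(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._resolve(self.samples.index, mask_or_ids)
        return GenotypeMatrix(self.calls[idx], self.samples.iloc[idx], self.snps)

    def take_snps(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._resolve(self.snps.index, mask_or_ids)
        return GenotypeMatrix(self.calls[:, idx], self.samples, self.snps.iloc[idx])

    @staticmethod
    def _resolve(index: pd.Index, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        locs = index.get_indexer(arr)
        if (locs < 0).any():
            missing = list(np.asarray(mask_or_ids)[locs < 0][:5])
            raise KeyError(f"ids not in registry: {missing}")
        return locs

    def with_metadata(self, metadata: pd.DataFrame) -> "GenotypeMatrix":
        """Attach a sample-metadata table (indexed or keyed by sample_id)."""
        md = metadata.copy()
        if "sample_id" in md.columns:
            md = md.set_index("sample_id")
        absent = self.samples.index.difference(md.index)
        if len(absent):
            raise ConfigurationError(
                f"metadata missing for samples: {list(absent[:5])}"
            )
        merged = self.samples.copy()
        for col in md.columns:
            merged[col] = md.reindex(self.samples.index)[col]
        return GenotypeMatrix(self.calls, merged, self.snps)


# ---------------------------------------------------------------------------
# PLINK text reading
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 4:
                chrom, mid, _cm, pos = tok
            elif len(tok) == 3:
                chrom, mid, pos = tok
            else:
                raise PlinkFormatError(
                    f"{map_path}: line {ln}: expected 3 or 4 columns, got {len(tok)}"
                )
            rows.append((mid, chrom, int(pos)))
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])
    return df.set_index("marker_id")


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a whitespace-delimited PED/MAP pair into a :class:`GenotypeMatrix`.

    The six leading PED columns (family, sample, father, mother, sex,
    phenotype) are accepted; only the sample id is kept. ``0 0`` genotype
    pairs become missing calls. Dosages count copies of the lexicographically
    larger observed allele at each marker.
    """
    snp_df = _read_map(map_path)
    m = len(snp_df)
    sample_ids: list[str] = []
    a1_rows: list[np.ndarray] = []
    a2_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6 or (len(tok) - 6) % 2:
                raise PlinkFormatError(
                    f"{ped_path}: line {ln}: ragged row with {len(tok)} fields"
                )
            npairs = (len(tok) - 6) // 2
            if npairs != m:
                raise PlinkFormatError(
                    f"{ped_path}: line {ln}: {npairs} genotype pairs but MAP has {m} markers"
                )
            sample_ids.append(tok[1])
            alleles = np.asarray(tok[6:], dtype=object)
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])
    if not sample_ids:
        raise PlinkFormatError(f"{ped_path}: no samples")
    a1 = np.vstack(a1_rows)  # (n, m) allele characters
    a2 = np.vstack(a2_rows)

    calls = np.full(a1.shape, np.nan)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        observed = sorted(set(col) - {MISSING_ALLELE})
        if len(observed) > 2:
            raise PlinkFormatError(
                f"marker {snp_df.index[j]}: more than 2 alleles observed: {observed}"
            )
        if len(observed) == 2:
            allele_a[j], allele_b[j] = observed
        elif len(observed) == 1:
            allele_a[j], allele_b[j] = observed[0], MISSING_ALLELE
        else:
            allele_a[j], allele_b[j] = "N", MISSING_ALLELE
        ok = (a1[:, j] != MISSING_ALLELE) & (a2[:, j] != MISSING_ALLELE)
        dose = (a1[:, j] == allele_b[j]).astype(float) + (a2[:, j] == allele_b[j])
        calls[ok, j] = dose[ok]

    snp_df = snp_df.assign(allele_a=allele_a, allele_b=allele_b)
    sample_df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    if not sample_df.index.is_unique:
        raise PlinkFormatError(f"{ped_path}: duplicate sample ids")
    return GenotypeMatrix(calls, sample_df, snp_df)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample-metadata sidecar."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ConfigurationError(f"{path}: expected a 'sample_id' column")
    return df.set_index("sample_id")


def read_marker_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    if "marker_id" not in df.columns:
        raise ConfigurationError(f"{path}: expected a 'marker_id' column")
    return df.set_index("marker_id")


def read_dataset(out_dir, prefix: str = "genotypes") -> GenotypeMatrix:
    """Read a PED/MAP pair plus the sample- and marker-metadata sidecars
    written by :func:`write_outputs`, restoring the exact dosage coding.

    PED text alone cannot fix the coding of a marker whose second allele is
    unobserved in the file; the marker TSV carries the allele pair, and
    dosages are re-expressed on it, making write -> read the identity.
    """
    out_dir = Path(out_dir)
    gm = read_plink_text(out_dir / f"{prefix}.ped", out_dir / f"{prefix}.map")
    markers = read_marker_metadata(out_dir / f"{prefix}.markers.tsv")
    if not markers.index.equals(gm.marker_ids):
        raise PlinkFormatError(f"{prefix}.markers.tsv does not match the MAP marker order")
    calls = gm.calls.copy()
    for j, mid in enumerate(gm.marker_ids):
        inferred = (str(gm.snps["allele_a"].iloc[j]), str(gm.snps["allele_b"].iloc[j]))
        target = (str(markers["allele_a"].iloc[j]), str(markers["allele_b"].iloc[j]))
        if inferred != target:
            calls[:, j] = _recode_to(calls[:, j], inferred, target)
    snp_df = markers.copy()
    gm = GenotypeMatrix(calls, gm.samples, snp_df)
    samples = read_sample_metadata(out_dir / f"{prefix}.samples.tsv")
    return gm.with_metadata(samples)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_snps_by_missingness(gm: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop SNPs with strictly more than ``max_missing_fraction`` missing calls."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = gm.missing_fraction_per_snp() <= max_missing_fraction
    return gm.take_snps(keep)


def filter_samples_by_missingness(gm: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop samples with strictly more than ``max_missing_fraction`` missing calls."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = gm.missing_fraction_per_sample() <= max_missing_fraction
    if not keep.any():
        raise ValueError("missingness filter removed every sample")
    return gm.take_samples(keep)


def filter_snps_by_gentrain(gm: GenotypeMatrix, min_score: float) -> GenotypeMatrix:
    """Keep SNPs whose clustering-quality (GenTrain) score is >= ``min_score``.

    The score is an Illumina chip artifact; this filter is optional and
    requires the ``gentrain_score`` column to be populated.
    """
    if "gentrain_score" not in gm.snps.columns or gm.snps["gentrain_score"].isna().any():
        raise ConfigurationError(
            "gentrain_score absent for some markers; this filter is optional and "
            "requires a populated gentrain_score column in the marker registry"
        )
    keep = (gm.snps["gentrain_score"] >= min_score).to_numpy()
    return gm.take_snps(keep)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _recode_to(calls_col: np.ndarray, pair, target_pair) -> np.ndarray:
    """Re-express one marker's dosage column on a new (allele_a, allele_b)."""
    a, b = pair
    ta, tb = target_pair
    if b == tb and a == ta:
        return calls_col
    if b == MISSING_ALLELE:  # monomorphic source: every non-missing call is hom a
        out = np.where(np.isnan(calls_col), np.nan, 2.0 if a == tb else 0.0)
        return out
    if b == ta and a == tb:
        return 2.0 - calls_col
    # source biallelic, target monomorphic or partial overlap handled upstream
    if b == tb:
        return calls_col
    if b == ta:
        return 2.0 - calls_col
    raise PlinkFormatError(f"cannot recode alleles {pair} onto {target_pair}")


def merge_datasets(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    allele_remap: dict[str, dict[str, str]] | None = None,
) -> GenotypeMatrix:
    """Union of samples over the intersection of markers.

    Shared markers must carry consistent allele pairs; conflicting pairs
    (e.g. A/G in one file, C/T in the other) raise a
    :class:`PlinkFormatError` naming the marker. Strand flips are never
    resolved silently — pass ``allele_remap`` ({marker_id: {old: new}},
    applied to ``b``) as the explicit escape hatch. Dosages are re-expressed
    on a common ``allele_b`` (lexicographically larger of the union of
    observed alleles).
    """
    overlap_samples = a.sample_ids.intersection(b.sample_ids)
    if len(overlap_samples):
        raise ValueError(f"sample ids present in both datasets: {list(overlap_samples[:5])}")
    common = a.marker_ids.intersection(b.marker_ids)
    common = a.marker_ids[a.marker_ids.isin(common)]  # keep a's order
    if not len(common):
        raise ValueError("no markers in common between the two datasets")

    ga = a.take_snps(common)
    gb = b.take_snps(common)
    allele_remap = allele_remap or {}

    calls = np.full((ga.n_samples + gb.n_samples, len(common)), np.nan)
    allele_a = np.empty(len(common), dtype=object)
    allele_b = np.empty(len(common), dtype=object)
    for j, mid in enumerate(common):
        pa = (str(ga.snps["allele_a"].iloc[j]), str(ga.snps["allele_b"].iloc[j]))
        pb = (str(gb.snps["allele_a"].iloc[j]), str(gb.snps["allele_b"].iloc[j]))
        remap = allele_remap.get(mid, {})
        pb = tuple(remap.get(x, x) for x in pb)
        observed = sorted(
            ({pa[0], pa[1], pb[0], pb[1]} - {MISSING_ALLELE, "N"})
        )
        if len(observed) > 2:
            raise PlinkFormatError(
                f"marker {mid}: conflicting allele pairs {pa} vs {pb}"
            )
        if len(observed) == 2:
            target = (observed[0], observed[1])
        elif len(observed) == 1:
            target = (observed[0], MISSING_ALLELE)
        else:
            target = ("N", MISSING_ALLELE)
        allele_a[j], allele_b[j] = target
        calls[: ga.n_samples, j] = _recode_to(ga.calls[:, j], pa, target)
        calls[ga.n_samples :, j] = _recode_to(gb.calls[:, j], pb, target)

    snps = ga.snps.copy()
    snps["allele_a"] = allele_a
    snps["allele_b"] = allele_b
    if "gentrain_score" not in snps.columns and "gentrain_score" in gb.snps.columns:
        snps["gentrain_score"] = gb.snps["gentrain_score"].to_numpy()
    samples = pd.concat([a.samples, b.samples])
    return GenotypeMatrix(calls, samples, snps)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_outputs(gm: GenotypeMatrix, out_dir, prefix: str = "genotypes") -> dict[str, Path]:
    """Write PED/MAP plus sample- and marker-metadata TSVs.

    ``read_plink_text`` on the written PED/MAP reproduces the calls array,
    marker order and sample order exactly.
    """
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ped = out_dir / f"{prefix}.ped"
    map_ = out_dir / f"{prefix}.map"
    samples_tsv = out_dir / f"{prefix}.samples.tsv"
    markers_tsv = out_dir / f"{prefix}.markers.tsv"

    aa = gm.snps["allele_a"].astype(str).to_numpy()
    ab = gm.snps["allele_b"].astype(str).to_numpy()
    with open(ped, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fam = gm.samples["landrace"].iloc[i] if "landrace" in gm.samples.columns else "FAM"
            if pd.isna(fam):
                fam = "FAM"
            fields = [str(fam), str(sid), "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                elif d == 0:
                    fields += [aa[j], aa[j]]
                elif d == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")
    with open(map_, "w") as fh:
        for mid, row in gm.snps.iterrows():
            fh.write(f"{row['chromosome']} {mid} 0 {int(row['position'])}\n")

    gm.samples.rename_axis("sample_id").reset_index().to_csv(samples_tsv, sep="\t", index=False)
    gm.snps.rename_axis("marker_id").reset_index().to_csv(markers_tsv, sep="\t", index=False)
    return {"ped": ped, "map": map_, "samples": samples_tsv, "markers": markers_tsv}
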