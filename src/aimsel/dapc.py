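"""Discriminant analysis of principal components (DAPC).

DAPC classifies samples into predefined groups by first reducing the dosage
matrix to its leading principal components and then finding linear
combinations of those components (discriminant functions) that maximize
between-group relative to within-group variance. Back-projecting the
discriminant axes through the PCA loadings gives a coefficient per original
marker per function; the squared, normalized coefficients are the marker
*contributions*, and the upper tail of the contribution distribution defines
the group-informative marker panel.

Usage follows the model/results convention::

    model = DAPC(gm, grouping, n_pca=4, n_disc=2)
    res = model.fit()
    print(res.summary())
    membership = res.predict()
    panel = select_informative(res.contributions(1), TopFraction(0.02))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .decompose import PcaResult, run_pca
from .fst import Grouping, SnpSet


@dataclass
class MembershipTable:
    """Posterior group-membership probabilities; rows sum to 1."""

    posteriors: pd.DataFrame  # samples x group labels
    assigned: pd.Series       # argmax label per sample


@dataclass
class ContributionProfile:
    """Per-marker contributions of one discriminant function (sum to 1)."""

    function_index: int | None  # 1-based; None = eigenvalue-weighted combination
    contributions: pd.Series    # marker_id -> contribution in [0, 1]
    rule: str = ""


class DAPC:
    """Discriminant analysis of principal components for a grouped cohort.

    Parameters
    ----------
    gm : GenotypeMatrix
        Training genotypes; missing calls are mean-imputed inside the PCA.
    grouping : Grouping
        Partition of the samples into k >= 2 groups (e.g. landrace labels or
        a low/high altitude dichotomy).
    n_pca : int, optional
        Number of leading principal components retained before the
        discriminant step. Defaults to the full rank of the centered matrix.
    n_disc : int, optional
        Number of discriminant functions, at most min(n_pca, k-1) (default).
    scale : bool
        Scale markers to unit variance before the PCA (off by default:
        dosages share units).
    """

    def __init__(self, gm, grouping: Grouping, n_pca: int | None = None,
                 n_disc: int | None = None, scale: bool = False):
        if grouping.k < 2:
            raise ValueError("DAPC needs at least 2 groups")
        self.gm = gm
        self.grouping = grouping
        self.n_pca = n_pca
        self.n_disc = n_disc
        self.scale = scale

    def fit(self) -> "DAPCResults":
        pca = run_pca(self.gm, scale=self.scale)
        rank = int((pca.explained_variance > 1e-12).sum())
        n_pca = self.n_pca if self.n_pca is not None else max(rank, 1)
        if not 1 <= n_pca <= pca.n_components:
            raise ValueError(f"n_pca must be in [1, {pca.n_components}]")
        k = self.grouping.k
        n_disc_max = min(n_pca, k - 1)
        n_disc = self.n_disc if self.n_disc is not None else n_disc_max
        if not 1 <= n_disc <= n_disc_max:
            raise ValueError(f"n_disc must be in [1, min(n_pca, k-1)] = [1, {n_disc_max}]")

        x = pca.scores[:, :n_pca]
        n = x.shape[0]
        idx = self.grouping.indices_for(self.gm.sample_ids)
        mu = x.mean(axis=0)
        within = np.zeros((n_pca, n_pca))
        between = np.zeros((n_pca, n_pca))
        means = {}
        for g, rows in idx.items():
            xg = x[rows]
            mg = xg.mean(axis=0)
            means[g] = mg
            within += (xg - mg).T @ (xg - mg)
            dm = (mg - mu)[:, None]
            between += len(rows) * (dm @ dm.T)
        within /= max(n - k, 1)
        between /= max(k - 1, 1)

        ridge = 0.0
        w_eigs = np.linalg.eigvalsh(within)
        if w_eigs.min() <= 1e-10 * max(np.trace(within) / n_pca, 1e-300):
            ridge = 1e-8 * np.trace(within) / n_pca
            if ridge <= 0:
                ridge = 1e-12
            warnings.warn(
                f"within-group covariance singular; ridge {ridge:.3g} added", stacklevel=2
            )
        evals, evecs = scipy.linalg.eigh(between, within + ridge * np.eye(n_pca))
        order = np.argsort(evals)[::-1][:n_disc]
        eigenvalues = evals[order]
        axes = evecs[:, order]  # n_pca x n_disc, scipy normalizes a'Wa = 1

        var_coeff = pca.loadings[:, :n_pca] @ axes  # markers x n_disc
        for f in range(n_disc):
            i = int(np.argmax(np.abs(var_coeff[:, f])))
            if var_coeff[i, f] < 0:
                axes[:, f] *= -1
                var_coeff[:, f] *= -1
        centroids = pd.DataFrame(
            {g: means[g] @ axes for g in self.grouping.groups},
            index=[f"LD{f+1}" for f in range(n_disc)],
        ).T

        return DAPCResults(
            model=self,
            pca=pca,
            n_pca=n_pca,
            n_disc=n_disc,
            disc_eigvec=axes,
            eigenvalues=eigenvalues,
            group_centroids=centroids,
            var_coeff=pd.DataFrame(
                var_coeff, index=self.gm.marker_ids,
                columns=[f"LD{f+1}" for f in range(n_disc)],
            ),
            ridge=ridge,
        )


@dataclass
class DAPCResults:
    """Fitted discriminant functions, centroids and per-marker coefficients."""

    model: DAPC
    pca: PcaResult
    n_pca: int
    n_disc: int
    disc_eigvec: np.ndarray          # n_pca x n_disc
    eigenvalues: np.ndarray          # between/within variance ratio per function
    group_centroids: pd.DataFrame    # groups x discriminant functions
    var_coeff: pd.DataFrame          # markers x discriminant functions
    ridge: float = 0.0

    @property
    def groups(self) -> list[str]:
        return self.model.grouping.groups

    def _project(self, gm=None) -> tuple[np.ndarray, pd.Index]:
        if gm is None:
            z = self.pca.scores[:, : self.n_pca] @ self.disc_eigvec
            return z, self.model.gm.sample_ids
        locs = gm.marker_ids.get_indexer(self.pca.marker_ids)
        if (locs < 0).any():
            missing = list(self.pca.marker_ids[locs < 0][:10])
            raise ValueError(f"query matrix lacks model markers: {missing}")
        calls = gm.calls[:, locs]
        scores = self.pca.transform(calls)[:, : self.n_pca]
        return scores @ self.disc_eigvec, gm.sample_ids

    def predict(self, gm=None) -> MembershipTable:
        """Posterior membership per sample: equal priors, unit isotropic
        covariance in discriminant space, P(g) proportional to exp(-d_g^2/2)."""
        z, sample_ids = self._project(gm)
        cent = self.group_centroids.to_numpy()
        d2 = ((z[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        log_post = -0.5 * d2
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        posteriors = pd.DataFrame(post, index=sample_ids, columns=self.groups)
        assigned = posteriors.idxmax(axis=1).rename("assigned")
        return MembershipTable(posteriors=posteriors, assigned=assigned)

    def accuracy(self, truth: Grouping | None = None, gm=None) -> float:
        """Percent of samples whose assigned group matches the truth
        (self-classification on the training set by default)."""
        membership = self.predict(gm)
        truth = truth or self.model.grouping
        return accuracy(membership, truth)

    def contributions(self, function_index: int | None = 1) -> ContributionProfile:
        """Per-marker contribution to one discriminant function.

        contribution_j = coeff_j^2 / sum_j coeff_j^2 for the chosen function;
        ``function_index=None`` returns the eigenvalue-weighted combination
        across all functions (still summing to 1).
        """
        if function_index is None:
            ev = np.clip(self.eigenvalues, 0, None)
            weights = ev / ev.sum() if ev.sum() > 0 else np.full(self.n_disc, 1 / self.n_disc)
            per_func = self.var_coeff.to_numpy() ** 2
            denom = per_func.sum(axis=0, keepdims=True)
            per_func = np.divide(per_func, denom, out=np.zeros_like(per_func), where=denom > 0)
            vals = per_func @ weights
        else:
            if not 1 <= function_index <= self.n_disc:
                raise ValueError(f"function_index must be in [1, {self.n_disc}]")
            col = self.var_coeff.iloc[:, function_index - 1].to_numpy()
            total = float((col**2).sum())
            vals = col**2 / total if total > 0 else np.zeros_like(col)
        return ContributionProfile(
            function_index=function_index,
            contributions=pd.Series(vals, index=self.var_coeff.index, name="contribution"),
        )

    def summary(self) -> str:
        acc = self.accuracy()
        counts = self.model.grouping.assignment.value_counts()
        lines = [
            "Discriminant Analysis of Principal Components",
            "=" * 46,
            f"Samples:                {self.pca.scores.shape[0]}",
            f"Markers:                {len(self.var_coeff)}",
            f"Groups ({len(self.groups)}):           "
            + ", ".join(f"{g} (n={counts[g]})" for g in self.groups),
            f"Retained PCs:           {self.n_pca}"
            + f"  ({100 * self.pca.explained_variance[: self.n_pca].sum():.1f}% variance)",
            f"Discriminant functions: {self.n_disc}",
            "Eigenvalues:            "
            + ", ".join(f"{v:.3f}" for v in self.eigenvalues),
            f"Self-assignment:        {acc:.1f}% correct",
        ]
        if self.ridge:
            lines.append(f"Ridge on within-cov:    {self.ridge:.3g}")
        return "\n".join(lines)


def accuracy(membership: MembershipTable, truth: Grouping) -> float:
    """100 x fraction of samples whose assignment matches the true group."""
    truth_labels = truth.assignment.reindex(membership.assigned.index)
    if truth_labels.isna().any():
        raise ValueError("truth grouping does not cover all classified samples")
    return float(100.0 * (membership.assigned == truth_labels).mean())


# ---------------------------------------------------------------------------
# Informative-marker selection rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopFraction:
    """Select the top ceil(q*N) contributors, ties at the cut included."""
    q: float

    def __str__(self) -> str:
        return f"top_fraction({self.q})"


@dataclass(frozen=True)
class TopCount:
    """Select the top m contributors, ties at the cut included."""
    m: int

    def __str__(self) -> str:
        return f"top_count({self.m})"


@dataclass(frozen=True)
class MeanPlusSd:
    """Select contributors strictly above mean + t*sd."""
    t: float

    def __str__(self) -> str:
        return f"mean_plus_sd({self.t})"


def select_informative(profile: ContributionProfile, rule) -> SnpSet:
    """Deterministic tail selection on a contribution profile.

    Count-based rules are ties-inclusive (every marker matching the cut value
    is kept, so the realized count may exceed the nominal one); the
    mean-plus-sd rule is strict, so a flat profile selects nothing.
    """
    vals = profile.contributions
    n = len(vals)
    if isinstance(rule, TopFraction):
        if not 0 < rule.q <= 1:
            raise ValueError("q must be in (0, 1]")
        m = math.ceil(rule.q * n)
    elif isinstance(rule, TopCount):
        m = int(rule.m)
    elif isinstance(rule, MeanPlusSd):
        m = None
    else:
        raise TypeError(f"unknown selection rule: {rule!r}")

    arr = vals.to_numpy()
    if m is not None:
        if m <= 0:
            warnings.warn(f"rule {rule} selects no markers", stacklevel=2)
            return SnpSet(name="informative", members=set(), provenance=f"rule={rule}; empty")
        m = min(m, n)
        thr = float(np.sort(arr)[::-1][m - 1])
        members = set(vals.index[arr >= thr])
    else:
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        thr = float(arr.mean() + rule.t * sd)
        members = set(vals.index[arr > thr])
    if not members:
        warnings.warn(f"rule {rule} selected no markers", stacklevel=2)
    fn = profile.function_index if profile.function_index is not None else "combined"
    return SnpSet(
        name=f"informative_fn{fn}",
        members=members,
        provenance=f"rule={rule}, realized_threshold={thr:.6g}, count={len(members)}, function={fn}",
    )
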