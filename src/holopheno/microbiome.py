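"""Root-microbiome OTU-table analyses.

Colonization robustness of SynCom members and enrichment/depletion of the
resident microbiota are assessed per OTU by a two-group Kruskal-Wallis test
on relative abundances (inoculated vs uninoculated arms), with an exact
permutation p-value at the small replicate numbers typical of these designs
(the asymptotic chi-square approximation is poor at n = 4 + 4).  Community
structure is compared via Bray-Curtis dissimilarities, principal-coordinates
analysis, and ANOSIM with seeded permutations.

No multiple-testing correction is applied by default (per-OTU P < 0.05); a
Benjamini-Hochberg option is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OtuTable",
    "relative_abundance",
    "kw_test",
    "classify_robust_colonizers",
    "classify_enriched_depleted",
    "bray_curtis",
    "PcoaResult",
    "pcoa",
    "AnosimResult",
    "anosim",
]


@dataclass
class OtuTable:
    """OTU x sample counts with taxonomy, SynCom flags and sample metadata.

    ``counts`` rows are OTUs, columns samples; ``sample_meta`` is indexed by
    sample id with columns ``hybrid``, ``inoculated`` (0/1), ``regime`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    syncom: pd.Series
    isolate: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not self.counts.index.equals(self.syncom.index):
            raise ValueError("syncom flags must be indexed by the OTU ids")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def syncom_otus(self) -> pd.Index:
        return self.counts.index[self.syncom.to_numpy(dtype=bool)]

    @property
    def resident_otus(self) -> pd.Index:
        return self.counts.index[~self.syncom.to_numpy(dtype=bool)]

    def samples_where(self, **conditions) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        mask = np.ones(len(meta), dtype=bool)
        for col, val in conditions.items():
            mask &= (meta[col] == val).to_numpy()
        return list(meta.index[mask])

    def to_tsv(self, counts_path, meta_path) -> None:
        out = self.counts.copy()
        out["taxonomy"] = self.taxonomy
        out["syncom_isolate"] = self.isolate.where(self.syncom, "")
        out.to_csv(counts_path, sep="\t", index_label="otu_id")
        self.sample_meta.to_csv(meta_path)

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "OtuTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col="otu_id")
        iso = raw.pop("syncom_isolate").fillna("")
        tax = raw.pop("taxonomy").fillna("")
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(
            counts=raw.astype(int),
            taxonomy=tax,
            syncom=iso.astype(str).str.len() > 0,
            isolate=iso.astype(str),
            sample_meta=meta,
        )


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample OTU proportions (columns sum to one)."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    return table.counts / totals


def syncom_aggregate(table: OtuTable) -> pd.Series:
    """Summed relative abundance of SynCom-flagged OTUs per sample."""
    rel = relative_abundance(table)
    return rel.loc[table.syncom_otus].sum(axis=0)


def _kw_h(ranks_a: np.ndarray, ranks_b: np.ndarray, tie_term: float, n: int) -> float:
    grand = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        ranks_a.size * (ranks_a.mean() - grand) ** 2
        + ranks_b.size * (ranks_b.mean() - grand) ** 2
    )
    return h / tie_term if tie_term > 0 else 0.0


def kw_test(a, b, mode: str = "auto", exact_max_n: int = 10) -> tuple[float, float]:
    """Two-group Kruskal-Wallis test with tie correction.

    ``mode``: ``"chi2"`` (asymptotic, df = 1), ``"exact"`` (full enumeration
    of all group labelings of the pooled ranks), or ``"auto"`` (exact when
    the pooled sample size is at most ``exact_max_n``).  Constant pooled
    data gives (H, p) = (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("kw_test requires at least two values per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    h = _kw_h(ranks[: a.size], ranks[a.size :], tie_term, n)
    if mode == "auto":
        mode = "exact" if n <= exact_max_n else "chi2"
    if mode == "chi2":
        p = float(stats.chi2.sf(h, df=1))
    elif mode == "exact":
        p = _kw_exact_p(ranks, a.size, h, tie_term)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(h), p


def _kw_exact_p(ranks: np.ndarray, n_a: int, h_obs: float, tie_term: float) -> float:
    """Exact p: fraction of the C(n, n_a) labelings with H >= observed."""
    n = ranks.size
    total = 0
    ge = 0
    for combo in itertools.combinations(range(n), n_a):
        idx = np.zeros(n, dtype=bool)
        idx[list(combo)] = True
        h = _kw_h(ranks[idx], ranks[~idx], tie_term, n)
        total += 1
        if h >= h_obs - 1e-12:
            ge += 1
    return ge / total


def _per_otu_tests(
    table: OtuTable,
    otus: pd.Index,
    groupers: list[str],
    alpha: float,
    mode: str,
    bh: bool,
) -> pd.DataFrame:
    """KW test per OTU within each metadata stratum, inoculated vs not."""
    rel = relative_abundance(table)
    meta = table.sample_meta.loc[list(table.counts.columns)]
    rows = []
    strata = meta.groupby(groupers, observed=True).groups if groupers else {(): meta.index}
    for key, samples in strata.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = meta.loc[samples]
        inoc = list(sub.index[sub["inoculated"] == 1])
        uninoc = list(sub.index[sub["inoculated"] == 0])
        testable = len(inoc) >= 2 and len(uninoc) >= 2
        a_mat = rel.loc[otus, inoc].to_numpy() if testable else None
        b_mat = rel.loc[otus, uninoc].to_numpy() if testable else None
        for i, otu_id in enumerate(otus):
            if not testable:
                rows.append(
                    dict(zip(groupers, key))
                    | {"otu_id": otu_id, "h": np.nan, "p_value": np.nan,
                       "median_inoculated": np.nan, "median_uninoculated": np.nan,
                       "testable": False}
                )
                continue
            h, p = kw_test(a_mat[i], b_mat[i], mode=mode)
            rows.append(
                dict(zip(groupers, key))
                | {
                    "otu_id": otu_id,
                    "h": h,
                    "p_value": p,
                    "median_inoculated": float(np.median(a_mat[i])),
                    "median_uninoculated": float(np.median(b_mat[i])),
                    "testable": True,
                }
            )
    out = pd.DataFrame(rows)
    if bh and not out.empty:
        ok = out["testable"].to_numpy()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(
                out.loc[ok, "p_value"].to_numpy(), method="bh"
            )
        out["p_value"] = adj
    return out


def classify_robust_colonizers(
    table: OtuTable,
    alpha: float = 0.05,
    mode: str = "auto",
    per_hybrid: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Call each SynCom OTU robust or not per (hybrid x regime).

    An OTU is a *robust colonizer* in a stratum when its relative abundance
    differs between arms (Kruskal-Wallis p < alpha) *and* its median
    relative abundance is higher in inoculated samples — significance with
    the opposite direction would flag displacement, not colonization.  Set
    ``per_hybrid=False`` to pool hybrids within each regime.
    """
    groupers = ["hybrid", "regime"] if per_hybrid else ["regime"]
    calls = _per_otu_tests(table, table.syncom_otus, groupers, alpha, mode, bh)
    calls["robust"] = (
        calls["testable"]
        & (calls["p_value"] < alpha)
        & (calls["median_inoculated"] > calls["median_uninoculated"])
    )
    calls["isolate"] = table.isolate.reindex(calls["otu_id"]).to_numpy()
    return calls


def robust_rollup(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-regime rollup: OTUs (and isolates) robust in >= 1 hybrid."""
    rows = []
    for regime, sub in calls.groupby("regime", observed=True):
        robust = sub[sub["robust"]]
        rows.append(
            {
                "regime": regime,
                "n_robust_otus": robust["otu_id"].nunique(),
                "n_robust_isolates": robust["isolate"].nunique(),
                "robust_otus": sorted(robust["otu_id"].unique()),
            }
        )
    return pd.DataFrame(rows)


def classify_enriched_depleted(
    table: OtuTable,
    alpha: float = 0.05,
    mode: str = "auto",
    per_hybrid: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Label each resident (non-SynCom) OTU enriched/depleted/unchanged.

    Significant (p < alpha) with a higher inoculated median is *enriched*,
    with a lower inoculated median *depleted*, anything else *unchanged* —
    a partition of the tested OTUs.  Strata default to regime only (hybrids
    pooled); the per-regime sets can be combined with
    :func:`shifted_otu_sets`.
    """
    groupers = (["hybrid", "regime"] if per_hybrid else ["regime"])
    calls = _per_otu_tests(table, table.resident_otus, groupers, alpha, mode, bh)
    direction = np.sign(calls["median_inoculated"] - calls["median_uninoculated"])
    sig = calls["testable"] & (calls["p_value"] < alpha)
    calls["call"] = np.select(
        [sig & (direction > 0), sig & (direction < 0)],
        ["enriched", "depleted"],
        default="unchanged",
    )
    return calls


def shifted_otu_sets(calls: pd.DataFrame) -> dict:
    """Per-regime shifted-OTU sets plus their union and intersection."""
    per_regime = {
        regime: set(sub.loc[sub["call"] != "unchanged", "otu_id"])
        for regime, sub in calls.groupby("regime", observed=True)
    }
    sets = list(per_regime.values())
    return {
        "per_regime": per_regime,
        "union": set().union(*sets) if sets else set(),
        "intersection": set.intersection(*sets) if sets else set(),
    }


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    ``d(u, v) = 1 - 2 * sum_i min(u_i, v_i) / (sum_i u_i + sum_i v_i)``;
    accepts counts or proportions (OTUs x samples).  Two all-zero samples
    have an undefined distance and raise ``ValueError``.
    """
    mat = pd.DataFrame(matrix)
    x = mat.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("bray_curtis requires at least two samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = x.sum(axis=0)
    denom = totals[:, None] + totals[None, :]
    if np.any(denom == 0):
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    # sum of element-wise minima for all pairs
    mins = np.minimum(x[:, :, None], x[:, None, :]).sum(axis=0)
    d = 1.0 - 2.0 * mins / denom
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


@dataclass
class PcoaResult:
    """Classical-scaling ordination: coordinates, eigenvalues, proportions.

    ``eigenvalues`` includes any negative values (non-Euclidean input) —
    they are reported, not dropped; ``proportion_explained`` is relative to
    the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame, k: int = 2) -> PcoaResult:
    """Principal-coordinates analysis of a distance matrix.

    Eigendecomposition of the double-centered matrix ``-0.5 * J D^2 J``;
    axes are ordered by decreasing eigenvalue and scaled by sqrt(eigenvalue).
    If fewer than ``k`` positive eigenvalues exist, the result is truncated
    with a warning.
    """
    dm = pd.DataFrame(d)
    x = dm.to_numpy(dtype=float)
    if not np.allclose(x, x.T):
        raise ValueError("distance matrix must be symmetric")
    n = x.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (x**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-10).sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from {k} axes",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_sum = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=dm.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation p-value."""

    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, between: np.ndarray) -> float:
    m = ranks.size
    return (ranks[between].mean() - ranks[~between].mean()) / (m / 2.0)


def anosim(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/4) with
    M = n(n-1)/2 pairwise distances ranked with average ranks for ties.
    The p-value is ``(1 + #{permuted R >= observed}) / (1 + n_perm)`` under
    random relabelling of samples; with ``exhaustive=True`` all distinct
    label permutations are enumerated instead (small n only) and the
    p-value is the exact tail fraction.
    """
    dm = pd.DataFrame(d)
    labels = np.asarray(pd.Series(groups).reindex(dm.index) if isinstance(groups, dict)
                        else groups)
    if len(labels) != dm.shape[0]:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("anosim requires at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    x = dm.to_numpy(dtype=float)
    iu = np.triu_indices(x.shape[0], k=1)
    ranks = stats.rankdata(x[iu])
    codes = pd.factorize(labels)[0]

    def between_mask(c: np.ndarray) -> np.ndarray:
        return c[iu[0]] != c[iu[1]]

    r_obs = _anosim_r(ranks, between_mask(codes))
    if exhaustive:
        perms = set(itertools.permutations(codes))
        r_perm = np.array([_anosim_r(ranks, between_mask(np.array(p))) for p in perms])
        p = float(np.mean(r_perm >= r_obs - 1e-12))
        return AnosimResult(r=float(r_obs), p_value=p, n_permutations=len(perms))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anosim_r(ranks, between_mask(perm)) >= r_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return AnosimResult(r=float(r_obs), p_value=float(p), n_permutations=n_perm)
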