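"""Group-level network statistics.

Three levels of comparison are implemented, mirroring how frequency-specific
connectivity networks are compared between clinical groups:

* **Global**: each subject's adjacency matrix is reduced to the mean over
  unmasked edges; groups are compared per band with the Kruskal-Wallis
  one-way ANOVA.
* **Edge-wise**: a one-tailed Wilcoxon rank-sum test per unmasked edge and
  direction (A>B and B>A separately), Benjamini-Hochberg corrected at
  alpha = 0.05 over the edges of that band/mode/direction family.  The
  extent of the stronger-in-A network is the network density K =
  significant edges / unmasked edges.  The per-edge effect size is the
  rank-biserial correlation derived from the rank-sum U.
* **Trajectory**: subjects are grouped by their 1-year-to-2-year
  neurocognitive trajectory ("Typical-Mild" etc.); groups sharing the
  1-year label are compared on their global connectivity per band.

Rank-sum p-values use the exact distribution for small groups
(min(n) <= 10, no ties) and a tie-corrected normal approximation with
continuity correction otherwise; the normal path is vectorized over edges
and is cross-checked against scipy in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .fidelity import EdgeMask
from .sourcemodel import LeadFieldBundle

__all__ = [
    "GroupComparison",
    "add_trajectory",
    "effect_size",
    "rank_sum_one_tailed",
    "bh_reject",
    "global_mean_connectivity",
    "edgewise_comparison",
    "region_summaries",
    "spindle_removal_contrast",
    "trajectory_analysis",
]

logger = logging.getLogger(__name__)

EXCLUDED_TRAJECTORIES = ("Typical-Severe",)


@dataclass
class GroupComparison:
    """Edge-wise one-tailed comparison of two groups (direction A > B)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    p: np.ndarray  # (P, P) raw one-tailed p per edge, NaN where masked
    significant: np.ndarray  # (P, P) bool after BH
    effect: np.ndarray  # (P, P) rank-biserial effect size
    k: float  # network density
    alpha: float = 0.05
    band_fc: float | None = None
    mode: str | None = None
    n_edges: int = 0  # unmasked edge count (BH family size)
    meta: dict = field(default_factory=dict)

    @property
    def direction(self) -> str:
        return f"{self.group_a}>{self.group_b}"


def add_trajectory(manifest: pd.DataFrame) -> pd.DataFrame:
    """Derive the '1y-2y' trajectory label; flag excluded trajectories."""
    out = manifest.copy()
    out["trajectory"] = out["neuro_1y"] + "-" + out["neuro_2y"]
    out["trajectory_excluded"] = out["trajectory"].isin(EXCLUDED_TRAJECTORIES)
    return out


def effect_size(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-biserial correlation in [-1, 1]; +1 when x completely exceeds y.

    Equals (#pairs x>y - #pairs x<y) / (n_x * n_y), ties contributing to
    neither side.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).mean())


def _tie_term(column: np.ndarray) -> float:
    _, counts = np.unique(column, return_counts=True)
    return float(np.sum(counts**3 - counts))


def rank_sum_one_tailed(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-tailed (a > b) Wilcoxon rank-sum over columns.

    ``a`` (n_a, m) and ``b`` (n_b, m); returns ``(p, effect)`` arrays of
    length m.  Exact p-values (scipy) when min(n) <= exact_max_n and the
    column has no ties; otherwise tie-corrected normal approximation with
    continuity correction.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[0], b.shape[0]
    m = a.shape[1]
    comb = np.vstack([a, b])
    ranks = sst.rankdata(comb, axis=0)
    u_a = ranks[:na].sum(axis=0) - na * (na + 1) / 2.0  # counts a>b (+ half-ties)
    effect = 2.0 * u_a / (na * nb) - 1.0
    nn = na + nb
    mu = na * nb / 2.0
    p = np.ones(m)
    for k in range(m):
        col = comb[:, k]
        tie = _tie_term(col)
        if min(na, nb) <= exact_max_n and tie == 0:
            p[k] = sst.mannwhitneyu(a[:, k], b[:, k], alternative="greater", method="exact").pvalue
            continue
        var = na * nb / 12.0 * ((nn + 1) - tie / (nn * (nn - 1)))
        if var <= 0:  # constant edge across all subjects
            p[k] = 1.0
            continue
        z = (u_a[k] - mu - 0.5) / np.sqrt(var)
        p[k] = sst.norm.sf(z)
    return p, effect


def bh_reject(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over a p-value vector."""
    p = np.asarray(p, float)
    if p.size == 0:
        return np.zeros(0, bool)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def _subject_global_means(mats: np.ndarray) -> np.ndarray:
    """(n_subjects,) mean over unmasked off-diagonal cells per subject."""
    n = mats.shape[1]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        return np.array([np.nanmean(m[off]) for m in mats])


@dataclass
class GlobalConnectivityResult:
    means: pd.DataFrame  # band_fc, group, mean, n
    tests: pd.DataFrame  # band_fc, H, p
    subject_means: pd.DataFrame  # band_fc, subject index, group, value


def global_mean_connectivity(
    matrices: dict[float, np.ndarray],
    manifest: pd.DataFrame,
    grouping: str = "neuro_2y",
) -> GlobalConnectivityResult:
    """Per-group global mean connectivity per band, with Kruskal-Wallis tests.

    ``matrices`` maps band fc to an (n_subjects, P, P) array aligned with
    the manifest rows; masked cells are NaN.
    """
    labels = manifest[grouping].to_numpy()
    groups = pd.unique(labels)
    if len(groups) < 2 or any((labels == g).sum() < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    mean_rows, test_rows, subj_rows = [], [], []
    for fc, mats in matrices.items():
        gm = _subject_global_means(np.asarray(mats))
        samples = []
        for g in groups:
            vals = gm[labels == g]
            if np.all(np.isnan(vals)):
                raise ValueError(f"group {g!r} emptied by masking at band {fc}")
            samples.append(vals[np.isfinite(vals)])
            mean_rows.append(
                {"band_fc": fc, "group": g, "mean": float(np.nanmean(vals)), "n": int(np.isfinite(vals).sum())}
            )
        for i, (v, g) in enumerate(zip(gm, labels)):
            subj_rows.append({"band_fc": fc, "subject": i, "group": g, "value": v})
        allvals = np.concatenate(samples)
        if np.unique(allvals).size <= 1:
            h, pv = 0.0, 1.0  # identical data everywhere: degenerate tie case
        else:
            h, pv = sst.kruskal(*samples)
        test_rows.append({"band_fc": fc, "H": float(h), "p": float(pv)})
    return GlobalConnectivityResult(
        means=pd.DataFrame(mean_rows),
        tests=pd.DataFrame(test_rows),
        subject_means=pd.DataFrame(subj_rows),
    )


def edgewise_comparison(
    matrices_a: np.ndarray,
    matrices_b: np.ndarray,
    group_a: str = "A",
    group_b: str = "B",
    alpha: float = 0.05,
    band_fc: float | None = None,
    mode: str | None = None,
) -> GroupComparison:
    """One-tailed (A > B) rank-sum per unmasked edge with BH-FDR and density K.

    An edge enters the BH family only if it is finite for every subject of
    both groups (consistent masking).  Constant edges get p = 1.
    """
    A = np.asarray(matrices_a, float)
    B = np.asarray(matrices_b, float)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("group matrices have different parcel counts")
    if min(A.shape[0], B.shape[0]) < 3:
        raise ValueError("each group needs n >= 3")
    n = A.shape[1]
    iu = np.triu_indices(n, k=1)
    av = A[:, iu[0], iu[1]]
    bv = B[:, iu[0], iu[1]]
    unmasked = np.isfinite(av).all(axis=0) & np.isfinite(bv).all(axis=0)
    p_edges = np.full(iu[0].size, np.nan)
    es_edges = np.full(iu[0].size, np.nan)
    sig_edges = np.zeros(iu[0].size, bool)
    if unmasked.any():
        p_u, es_u = rank_sum_one_tailed(av[:, unmasked], bv[:, unmasked])
        p_edges[unmasked] = p_u
        es_edges[unmasked] = es_u
        sig_edges[unmasked] = bh_reject(p_u, alpha=alpha)
    n_edges = int(unmasked.sum())
    k = float(sig_edges.sum() / n_edges) if n_edges else 0.0

    def square(vec, fill=np.nan, dtype=float):
        m = np.full((n, n), fill, dtype=dtype)
        m[iu] = vec
        m.T[iu] = vec
        return m

    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=A.shape[0],
        n_b=B.shape[0],
        p=square(p_edges),
        significant=square(sig_edges, fill=False, dtype=bool),
        effect=square(es_edges),
        k=k,
        alpha=alpha,
        band_fc=band_fc,
        mode=mode,
        n_edges=n_edges,
    )


def region_summaries(
    comp: GroupComparison, bundle: LeadFieldBundle, mask: EdgeMask | None = None
) -> dict:
    """Region involvement, region-pair fractions, and edge-length distribution.

    Involvement of a region = significant edges incident to its parcels /
    possible (unmasked) edges incident to its parcels; region-pair fraction
    likewise between two regions.  Edge lengths are Euclidean centroid
    distances of the significant edges (report them on a log scale).
    """
    n = comp.p.shape[0]
    labels = np.array(bundle.region_labels)
    regions = sorted(set(labels))
    sig = comp.significant
    possible = np.isfinite(comp.p)
    if mask is not None:
        possible = possible & mask.include
    iu = np.triu_indices(n, k=1)

    involvement = {}
    for r in regions:
        inc = np.isin(labels[iu[0]], [r]) | np.isin(labels[iu[1]], [r])
        tot = int((possible[iu] & inc).sum())
        involvement[r] = float((sig[iu] & inc).sum() / tot) if tot else 0.0

    region_pairs = {}
    for i, r in enumerate(regions):
        for s in regions[i:]:
            sel = (
                ((labels[iu[0]] == r) & (labels[iu[1]] == s))
                | ((labels[iu[0]] == s) & (labels[iu[1]] == r))
            )
            tot = int((possible[iu] & sel).sum())
            if tot:  # region pairs with no possible edge are omitted
                region_pairs[(r, s)] = float((sig[iu] & sel).sum() / tot)

    hemi = np.array([lab.split("-")[1] for lab in labels])
    inter_sel = hemi[iu[0]] != hemi[iu[1]]
    tot_inter = int((possible[iu] & inter_sel).sum())
    tot_intra = int((possible[iu] & ~inter_sel).sum())
    inter = float((sig[iu] & inter_sel).sum() / tot_inter) if tot_inter else 0.0
    intra = float((sig[iu] & ~inter_sel).sum() / tot_intra) if tot_intra else 0.0

    d = np.linalg.norm(
        bundle.centroids[iu[0]] - bundle.centroids[iu[1]], axis=1
    )
    lengths = d[sig[iu]]
    return {
        "involvement": involvement,
        "region_pairs": region_pairs,
        "interhemispheric_fraction": inter,
        "intrahemispheric_fraction": intra,
        "edge_lengths": lengths,
    }


def spindle_removal_contrast(
    full: dict, removed: dict
) -> pd.DataFrame:
    """Paired K contrast between full and spindle-removed pipeline variants.

    ``full`` and ``removed`` map identical keys (e.g. (band_fc, mode)) to
    :class:`GroupComparison` objects computed on identical subjects.
    Returns per key: K_full, K_removed, delta_K (< 0 means the group
    difference shrank after removal).
    """
    if set(full) != set(removed):
        raise ValueError("full and spindle-removed variants cover different keys")
    rows = []
    for key in full:
        f, r = full[key], removed[key]
        if (f.n_a, f.n_b) != (r.n_a, r.n_b) or f.direction != r.direction:
            raise ValueError(f"variant mismatch for {key}: different subjects or direction")
        rows.append(
            {
                "key": key,
                "band_fc": f.band_fc,
                "mode": f.mode,
                "direction": f.direction,
                "k_full": f.k,
                "k_removed": r.k,
                "delta_k": r.k - f.k,
            }
        )
    return pd.DataFrame(rows)


def trajectory_analysis(
    matrices: dict[float, np.ndarray],
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 2,
) -> dict:
    """Connectivity by neurocognitive trajectory, with shared-1y-label tests.

    Groups below ``min_group`` subjects and excluded trajectories are
    dropped (logged).  For every pair of trajectory groups sharing the
    1-year label, global connectivity is compared per band (two-sided
    rank-sum), BH-corrected over bands within the comparison.
    """
    man = add_trajectory(manifest)
    keep = ~man["trajectory_excluded"]
    counts = man.loc[keep, "trajectory"].value_counts()
    groups = [g for g in counts.index if counts[g] >= min_group]
    for g in counts.index:
        if g not in groups:
            logger.info("trajectory group %s dropped (n=%d < %d)", g, counts[g], min_group)
    dropped_excl = man.loc[~keep, "trajectory"].unique().tolist()
    if dropped_excl:
        logger.info("excluded trajectories dropped: %s", dropped_excl)

    summary_rows, test_rows = [], []
    bands = sorted(matrices)
    gm_per_band = {
        fc: _subject_global_means(np.asarray(matrices[fc])) for fc in bands
    }
    for g in groups:
        sel = (man["trajectory"] == g).to_numpy() & keep.to_numpy()
        for fc in bands:
            vals = gm_per_band[fc][sel]
            summary_rows.append(
                {"trajectory": g, "band_fc": fc, "mean": float(np.nanmean(vals)), "n": int(sel.sum())}
            )
    pairs = [
        (g1, g2)
        for i, g1 in enumerate(groups)
        for g2 in groups[i + 1:]
        if g1.split("-")[0] == g2.split("-")[0]
    ]
    for g1, g2 in pairs:
        s1 = (man["trajectory"] == g1).to_numpy() & keep.to_numpy()
        s2 = (man["trajectory"] == g2).to_numpy() & keep.to_numpy()
        ps, ess = [], []
        for fc in bands:
            x, y = gm_per_band[fc][s1], gm_per_band[fc][s2]
            res = sst.mannwhitneyu(x, y, alternative="two-sided")
            ps.append(res.pvalue)
            ess.append(effect_size(x, y))
        rej = bh_reject(np.array(ps), alpha=alpha)
        for fc, pv, es, rj in zip(bands, ps, ess, rej):
            test_rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "band_fc": fc,
                    "p": float(pv),
                    "p_significant": bool(rj),
                    "effect": float(es),
                    "direction": f"{g1}>{g2}" if es > 0 else f"{g2}>{g1}",
                }
            )
    return {
        "summary": pd.DataFrame(summary_rows),
        "tests": pd.DataFrame(test_rows),
        "groups": groups,
    }
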