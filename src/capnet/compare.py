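"""Correspondence statistics between transient patterns and network maps.

Spatial similarity (Fisher-z correlation, dice on thresholded maps) with
permutation nulls, hemispheric symmetry, leave-one-out inter-participant
consistency, mixed-model group contrasts, and temporal correspondence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.formula.api as smf

from ._util import check_rng, mirror_permutation, pearson_rows

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Pattern-by-network similarity values plus matched pairs and p-values."""

    values: np.ndarray  # (n_cap, n_rsn)
    metric: str  # fisher_z | dice | temporal_z
    matched_pairs: list = field(default_factory=list)  # (cap_i, rsn_j[, hemisphere])
    p_matched_mean: float = None
    p_per_pair: dict = field(default_factory=dict)
    p_per_pair_corrected: dict = field(default_factory=dict)


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing atanh transform; |r| >= 1 is clipped first."""
    r = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1):
        warnings.warn("correlation(s) with |r| >= 1 clipped before Fisher z")
        r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def dice_score(
    mapA: np.ndarray,
    mapB: np.ndarray,
    threshold_frac: float = 0.2,
    use_abs: bool = False,
    mask: np.ndarray | None = None,
) -> float:
    """Dice overlap of the two maps binarized at a fraction of their own max.

    Maps are signed; by default the supra-threshold set is where the map
    exceeds ``threshold_frac`` times its positive maximum (``use_abs``
    switches to absolute values). An empty binarized map gives dice 0 with a
    warning.
    """
    a = np.asarray(mapA, dtype=float)
    b = np.asarray(mapB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have the same length")
    if mask is not None:
        a, b = a[mask], b[mask]
    if use_abs:
        a, b = np.abs(a), np.abs(b)
    A = a > threshold_frac * a.max()
    B = b > threshold_frac * b.max()
    if not A.any() or not B.any():
        warnings.warn("empty binarized map; dice defined as 0")
        return 0.0
    return 2.0 * np.sum(A & B) / (A.sum() + B.sum())


def match_maps(cap_maps: np.ndarray, rsn_maps: np.ndarray) -> list:
    """Optimal one-to-one matching maximizing total Fisher-z correlation."""
    r = pearson_rows(cap_maps, rsn_maps)
    z = fisher_z(r)
    rows, cols = scipy.optimize.linear_sum_assignment(-z)
    return [(int(i), int(j)) for i, j in zip(rows, cols)]


def similarity_confusion(
    cap_maps: np.ndarray,
    rsn_maps: np.ndarray,
    match_table: list | None = None,
    hemisphere_masks: dict | None = None,
    threshold_frac: float = 0.2,
) -> dict:
    """Full Fisher-z and dice confusion matrices with a matched-pair mask.

    ``match_table`` rows are (cap_i, rsn_j) or (cap_i, rsn_j, hemisphere);
    one-to-two matches carry a hemisphere tag and their similarity is
    evaluated inside that hemisphere's mask only. When no table is given,
    optimal one-to-one assignment on Fisher-z is used. Returns a dict with a
    SimilarityMatrix per metric.
    """
    cap_maps = np.atleast_2d(np.asarray(cap_maps, dtype=float))
    rsn_maps = np.atleast_2d(np.asarray(rsn_maps, dtype=float))
    if cap_maps.shape[1] != rsn_maps.shape[1]:
        raise ValueError("cap and rsn maps must share one spatial space")
    n_cap, n_rsn = cap_maps.shape[0], rsn_maps.shape[0]
    if match_table is None:
        match_table = match_maps(cap_maps, rsn_maps)
    for pair in match_table:
        i, j = pair[0], pair[1]
        if not (0 <= i < n_cap and 0 <= j < n_rsn):
            raise ValueError(f"match table references missing ids: {pair}")
        if len(pair) > 2 and pair[2] is not None:
            if hemisphere_masks is None or pair[2] not in hemisphere_masks:
                raise ValueError(f"no hemisphere mask for tag {pair[2]!r}")

    zmat = fisher_z(pearson_rows(cap_maps, rsn_maps))
    dmat = np.array(
        [
            [dice_score(cap_maps[i], rsn_maps[j], threshold_frac) for j in range(n_rsn)]
            for i in range(n_cap)
        ]
    )
    out = {
        "fisher_z": SimilarityMatrix(zmat, "fisher_z", list(match_table)),
        "dice": SimilarityMatrix(dmat, "dice", list(match_table)),
    }
    # hemisphere-restricted values replace the whole-map entry for tagged pairs
    for pair in match_table:
        if len(pair) > 2 and pair[2] is not None:
            i, j, hemi = pair[0], pair[1], pair[2]
            m = np.asarray(hemisphere_masks[hemi], dtype=bool)
            r = pearson_rows(cap_maps[i : i + 1, m], rsn_maps[j : j + 1, m])[0, 0]
            out["fisher_z"].values[i, j] = fisher_z(r)
            out["dice"].values[i, j] = dice_score(
                cap_maps[i], rsn_maps[j], threshold_frac, mask=m
            )
    return out


def permutation_match_test(
    sim: SimilarityMatrix,
    n_perm: int = 100_000,
    seed=0,
    alternative: str = "greater",
) -> SimilarityMatrix:
    """Permutation null for matched-pair similarity.

    Network column labels are relabeled uniformly at random (identity
    allowed) ``n_perm`` times; the null statistic is the mean similarity
    over the fixed matched mask. ``p = (1 + #{null >= observed}) / (1 +
    n_perm)``; per-pair p-values use the same draws per pair, Bonferroni
    corrected over the matched pairs.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refused")
    V = sim.values
    n_rsn = V.shape[1]
    if n_rsn < 2:
        raise ValueError("need at least 2 networks to permute")
    pairs = [(p[0], p[1]) for p in sim.matched_pairs]
    if not pairs:
        raise ValueError("no matched pairs to test")
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    observed = V[rows, cols]
    obs_mean = observed.mean()
    rng = check_rng(seed)
    perms = np.array([rng.permutation(n_rsn) for _ in range(n_perm)])  # (n_perm, n_rsn)
    null = V[rows[None, :], perms[:, cols]]  # (n_perm, n_pairs)
    null_mean = null.mean(axis=1)
    if alternative != "greater":
        raise NotImplementedError("only 'greater' is implemented")
    p_mean = (1 + int(np.sum(null_mean >= obs_mean))) / (1 + n_perm)
    n_pairs = len(pairs)
    p_pair, p_pair_corr = {}, {}
    counts = (null >= observed[None, :]).sum(axis=0)
    for idx, pair in enumerate(pairs):
        p = (1 + int(counts[idx])) / (1 + n_perm)
        p_pair[pair] = p
        p_pair_corr[pair] = min(1.0, p * n_pairs)
    return SimilarityMatrix(
        V, sim.metric, sim.matched_pairs, p_mean, p_pair, p_pair_corr
    )


def symmetry_index(map_vec: np.ndarray, mirror_pairs: np.ndarray,
                   partner: np.ndarray | None = None) -> float:
    """Pearson correlation between a map and its hemisphere-swapped copy.

    For a unilateral pattern pair, pass the partner map: the index is then
    the correlation between one member and the mirror of the other.
    """
    v = np.asarray(map_vec, dtype=float).ravel()
    perm = mirror_permutation(mirror_pairs, v.size)
    other = v if partner is None else np.asarray(partner, dtype=float).ravel()
    return float(pearson_rows(v[None, :], other[perm][None, :])[0, 0])


def loo_consistency(participant_maps: np.ndarray) -> np.ndarray:
    """Leave-one-out spatial consistency per participant.

    ``participant_maps`` is (n_participants x R) for one pattern; each
    participant's map is correlated with the mean of all the others.
    Participants with a missing (all-NaN) map get NaN.
    """
    M = np.atleast_2d(np.asarray(participant_maps, dtype=float))
    P = M.shape[0]
    if P < 3:
        raise ValueError("leave-one-out consistency needs >= 3 participants")
    present = ~np.all(np.isnan(M), axis=1)
    out = np.full(P, np.nan)
    for i in range(P):
        if not present[i]:
            continue
        others = M[present & (np.arange(P) != i)]
        if others.shape[0] == 0:
            continue
        ref = np.nanmean(others, axis=0)
        out[i] = pearson_rows(M[i][None, :], ref[None, :])[0, 0]
    return out


def consistency_table(
    participant_maps_by_pattern: dict,
    group_of_pattern: dict,
    pattern_type: str,
) -> pd.DataFrame:
    """Long-format LOO consistency table (Fisher z) for the mixed model."""
    rows = []
    for name, maps in participant_maps_by_pattern.items():
        r = loo_consistency(maps)
        for p, val in enumerate(r):
            if np.isfinite(val):
                rows.append(
                    {
                        "pattern": name,
                        "pattern_type": pattern_type,
                        "group": group_of_pattern[name],
                        "participant": p,
                        "r": val,
                        "z": fisher_z(val),
                    }
                )
    return pd.DataFrame(rows)


def consistency_mixed_model(table: pd.DataFrame) -> dict:
    """Mixed linear model on Fisher-z consistency.

    Fixed effects for pattern type (when both levels are present) and group,
    random intercept per participant, fitted by REML. Falls back to OLS when
    the mixed fit is singular or fails, with the event logged.
    """
    df = table.copy()
    df["group"] = pd.Categorical(df["group"], categories=["SM", "HO", "Other"])
    terms = ["C(group, Treatment('SM'))"]
    if df["pattern_type"].nunique() > 1:
        terms.insert(0, "C(pattern_type)")
    formula = "z ~ " + " + ".join(terms)
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["participant"])
            fit = model.fit(reml=True)
            singular = not np.all(np.isfinite(fit.bse_fe))
        except Exception:  # pragma: no cover - defensive
            singular = True
            fit = None
    if fit is None or singular:
        logger.warning("singular mixed fit; falling back to fixed-effects OLS")
        fit = smf.ols(formula, df).fit()
        fallback = True
    params = fit.params
    pvals = fit.pvalues
    return {
        "fit": fit,
        "fallback_ols": fallback,
        "coefficients": pd.DataFrame({"beta": params, "p": pvals}),
    }


def beta_consistency_correlation(
    participant_betas: np.ndarray,
    group_maps: np.ndarray,
    loo_scores: np.ndarray,
    mask_frac: float = 0.05,
) -> dict:
    """Correlate top-mask mean beta magnitude with LOO consistency.

    ``participant_betas`` is (n_components x n_participants x R),
    ``group_maps`` (n_components x R), ``loo_scores`` (n_components x
    n_participants). For each (component, participant) the mean beta inside
    the top ``mask_frac`` of the group map is pooled against consistency.
    """
    B = np.asarray(participant_betas, dtype=float)
    G = np.atleast_2d(np.asarray(group_maps, dtype=float))
    L = np.atleast_2d(np.asarray(loo_scores, dtype=float))
    xs, ys = [], []
    for c in range(G.shape[0]):
        n_top = max(1, int(round(mask_frac * G.shape[1])))
        mask = np.argsort(G[c])[-n_top:]
        for p in range(B.shape[1]):
            if np.isfinite(L[c, p]):
                xs.append(B[c, p, mask].mean())
                ys.append(L[c, p])
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.size < 3 or xs.std() == 0 or ys.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": int(xs.size)}
    r, p = scipy.stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": int(xs.size)}


def temporal_correspondence(
    cap_tc_by_participant: list,
    ic_env_by_participant: list,
    match_table: list | None = None,
    n_perm: int = 10_000,
    seed=0,
) -> SimilarityMatrix:
    """Participant-averaged Fisher-z temporal correlation, permutation tested.

    Per participant, each CAP time course is correlated with each component
    envelope over time; correlations are Fisher-z transformed and averaged
    across participants, then the matched-pair mean is tested against the
    column-relabeling null.
    """
    zs = []
    for cap_tc, ic_env in zip(cap_tc_by_participant, ic_env_by_participant):
        cap_tc = np.atleast_2d(cap_tc)
        ic_env = np.atleast_2d(ic_env)
        if cap_tc.shape[1] != ic_env.shape[1]:
            raise ValueError("time axes of CAP and component series differ")
        zs.append(fisher_z(pearson_rows(cap_tc, ic_env)))
    Z = np.nanmean(np.stack(zs), axis=0)
    if match_table is None:
        rows, cols = scipy.optimize.linear_sum_assignment(-Z)
        match_table = [(int(i), int(j)) for i, j in zip(rows, cols)]
    sim = SimilarityMatrix(Z, "temporal_z", list(match_table))
    return permutation_match_test(sim, n_perm=n_perm, seed=seed)
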