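"""Detection of induced protein translocations between organellar maps.

For each replicate pair of control and treated maps, the two profiles of
every protein are subtracted to give a delta profile.  Under the null
(no movement) delta profiles scatter around the center of the delta
matrix; a protein's squared robust Mahalanobis distance to that center
approximately follows a chi-square law and converts to a p value.  Two
summary scores are derived per protein:

* **M score** (magnitude): the largest of the replicate p values is
  taken (the smallest observed shift), raised to the power of the number
  of replicates (each replicate's p value is at most the chosen one),
  Benjamini-Hochberg corrected across proteins, and -log10-transformed.
* **R score** (reproducibility): the minimum pairwise Pearson
  correlation among the replicate delta profiles.

Genuine translocators score high in both dimensions.  Cutoffs on (M, R)
are chosen against a mock experiment (control vs control, where no
genuine movement exists): the empirical FDR of a cutoff pair is the mock
hit rate divided by the real hit rate, and the selected pair maximizes
real hits subject to the target FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .io_formats import MarkerTable, _write_with_header
from .profiling import ProfileMatrix, marker_assignments

P_FLOOR = 1e-300


@dataclass
class DeltaMatrix:
    """Per-protein delta profiles (treated - control) for each replicate pair."""

    protein_ids: pd.Index
    deltas: list[np.ndarray]  # one (n_proteins, F) array per replicate pair
    fractions: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.deltas)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


def delta_profiles(control: ProfileMatrix, treated: ProfileMatrix) -> DeltaMatrix:
    """Subtract paired control from treated profiles, replicate by replicate.

    The r-th replicate of ``treated`` is paired with the r-th replicate
    of ``control``; proteins are inner-joined.  Because both profiles sum
    to 1, every delta profile sums to 0.
    """
    if control.n_replicates != treated.n_replicates:
        raise ValueError(
            f"replicate pairing mismatch: {control.n_replicates} control vs "
            f"{treated.n_replicates} treated maps"
        )
    if control.fractions != treated.fractions:
        raise ValueError("control and treated maps use different fraction sets")
    shared = control.protein_ids.intersection(treated.protein_ids).sort_values()
    if len(shared) == 0:
        raise ValueError("no protein shared between control and treated maps")
    deltas = []
    for r in range(control.n_replicates):
        c = control.replicate_block(r).loc[shared].to_numpy()
        t = treated.replicate_block(r).loc[shared].to_numpy()
        deltas.append(t - c)
    return DeltaMatrix(shared, deltas, list(control.fractions))


def mahalanobis_sq(
    X: np.ndarray,
    robust: bool = True,
    seed: int = 0,
    support_fraction: float = 0.75,
    rank_tol: float = 1e-8,
) -> tuple[np.ndarray, int]:
    """Squared (robust) Mahalanobis distance of each row to the matrix center.

    Sum-zero delta profiles are rank deficient, so distances are computed
    in the span of the data: the top components of the centered matrix
    (singular value > ``rank_tol`` relative) define the working subspace,
    which is equivalent to a pseudo-inverse restricted to those
    components.  With ``robust=True`` the center and scatter come from a
    deterministic minimum-covariance-determinant fit (``support_fraction``
    of the points, seeded); otherwise the sample mean and covariance are
    used.  Returns the distances and the effective rank.
    """
    X = np.asarray(X, dtype=float)
    n, F = X.shape
    if n < F + 2:
        raise ValueError(f"need at least {F + 2} proteins to estimate scatter, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("delta matrix contains non-finite values")
    center = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - center, full_matrices=False)
    rank = int(np.sum(s > rank_tol * s[0])) if s[0] > 0 else 0
    if rank == 0:
        return np.zeros(n), 0
    Z = (X - center) @ Vt[:rank].T
    if robust:
        mcd = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(Z)
        d2 = mcd.mahalanobis(Z)
    else:
        mu = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        diff = Z - mu
        d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    return np.asarray(d2, dtype=float), rank


def pvalue_chi2(d2, df: int = 5):
    """Upper-tail chi-square probability of a squared Mahalanobis distance."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    d2 = np.asarray(d2, dtype=float)
    if (d2 < 0).any():
        raise ValueError("squared distances must be non-negative")
    return stats.chi2.sf(d2, df)


def m_scores(p_per_replicate: np.ndarray, n_replicates: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """M scores from an (n_proteins, n_replicates) matrix of raw p values.

    Per protein, the largest replicate p value is chosen, raised to the
    number of replicates, BH-adjusted across proteins (capped at 1), and
    -log10-transformed.  Returns (m_scores, adjusted_p).
    """
    P = np.asarray(p_per_replicate, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if not np.isfinite(P).all() or (P <= 0).any() or (P > 1).any():
        raise ValueError("p values must be finite and in (0, 1]")
    k = n_replicates if n_replicates is not None else P.shape[1]
    p_star = np.clip(P.max(axis=1), P_FLOOR, 1.0)
    cubed = np.clip(p_star**k, P_FLOOR, 1.0)
    q = multipletests(cubed, method="fdr_bh")[1]
    q = np.clip(q, P_FLOOR, 1.0)
    return -np.log10(q), q


def r_scores(deltas: DeltaMatrix, min_replicates: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Minimum pairwise Pearson correlation of the replicate delta profiles.

    The experimental design is triplicate (three pairwise correlations;
    the lowest is the R score); ``min_replicates=2`` relaxes this to the
    minimum over all pairs.  Proteins with a zero-variance delta in any
    replicate get R = 0 and are flagged as undefined.
    """
    R = deltas.n_pairs
    if R < min_replicates:
        raise ValueError(f"R scores require >= {min_replicates} replicate pairs, got {R}")
    n, F = deltas.n_proteins, len(deltas.fractions)
    Z = np.empty((R, n, F))
    degenerate = np.zeros(n, dtype=bool)
    for r, D in enumerate(deltas.deltas):
        mu = D.mean(axis=1, keepdims=True)
        sd = D.std(axis=1, keepdims=True)
        zero = sd[:, 0] == 0
        degenerate |= zero
        sd[zero] = 1.0
        Z[r] = (D - mu) / sd
    rmin = np.full(n, np.inf)
    for a in range(R):
        for b in range(a + 1, R):
            r_ab = np.mean(Z[a] * Z[b], axis=1)
            rmin = np.minimum(rmin, r_ab)
    rmin[degenerate] = 0.0
    return rmin, degenerate


def compute_mr(
    control: ProfileMatrix,
    treated: ProfileMatrix,
    robust: bool = True,
    seed: int = 0,
    df: int | None = None,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Full MR analysis of one comparative experiment.

    ``df`` defaults to the number of map fractions (the five-point-profile
    convention); the chi-square approximation is applied to the robust
    squared distances of each replicate's delta matrix.
    """
    dm = delta_profiles(control, treated)
    if df is None:
        df = len(dm.fractions)
    P = np.empty((dm.n_proteins, dm.n_pairs))
    for r, D in enumerate(dm.deltas):
        d2, _ = mahalanobis_sq(D, robust=robust, seed=seed)
        P[:, r] = np.clip(pvalue_chi2(d2, df=df), P_FLOOR, 1.0)
    m, q = m_scores(P)
    r, degenerate = r_scores(dm, min_replicates=min_replicates)
    p_cubed = np.clip(np.clip(P.max(axis=1), P_FLOOR, 1.0) ** dm.n_pairs, P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            **{f"p_rep{i + 1}": P[:, i] for i in range(dm.n_pairs)},
            "p_cubed": p_cubed,
            "p_adj": q,
            "m_score": m,
            "r_score": r,
            "r_undefined": degenerate,
        },
        index=dm.protein_ids,
    )
    return out


def flag_movers(mr: pd.DataFrame, m_cut: float, r_cut: float) -> pd.Series:
    return (mr["m_score"] >= m_cut) & (mr["r_score"] >= r_cut)


def estimate_fdr(m_cut: float, r_cut: float, real: pd.DataFrame, mock: pd.DataFrame) -> float:
    """Empirical FDR of a cutoff pair: mock hit rate over real hit rate.

    Hit rates are scaled by dataset sizes.  Returns 0 when the mock shows
    no hits but the real data does, and NaN when there is no real hit.
    """
    if len(real) == 0 or len(mock) == 0:
        raise ValueError("both real and mock score tables must be non-empty")
    hits_real = int(flag_movers(real, m_cut, r_cut).sum())
    hits_mock = int(flag_movers(mock, m_cut, r_cut).sum())
    if hits_real == 0:
        return float("nan")
    return (hits_mock / len(mock)) / (hits_real / len(real))


def mock_equivalent_m(real: pd.DataFrame, mock: pd.DataFrame) -> np.ndarray:
    """Mock M scores on the real experiment's scale.

    The M score is a within-dataset BH transform of the cubed worst-
    replicate p value, so the same numeric M cutoff corresponds to
    different raw-p thresholds in the real and mock datasets (genuine
    movers shift the real dataset's BH ranks).  To apply "the same
    cutoffs" to both, each mock protein's raw cubed p value is mapped
    through the real experiment's monotone p -> M relation: its
    equivalent M is the M score of the real protein with the smallest
    cubed p at or above it (-inf when it exceeds every real value).
    Requires the ``p_cubed`` column produced by :func:`compute_mr`.
    """
    order = np.argsort(real["p_cubed"].to_numpy())
    p_sorted = real["p_cubed"].to_numpy()[order]
    m_sorted = real["m_score"].to_numpy()[order]
    # enforce monotonicity (BH m is non-increasing in p up to float noise)
    m_sorted = np.maximum.accumulate(m_sorted[::-1])[::-1]
    idx = np.searchsorted(p_sorted, mock["p_cubed"].to_numpy(), side="left")
    out = np.full(len(mock), -np.inf)
    inside = idx < len(p_sorted)
    out[inside] = m_sorted[idx[inside]]
    return out


class CutoffSelection(NamedTuple):
    m_cut: float
    r_cut: float
    n_hits: int
    fdr: float


def select_cutoffs(
    target_fdr: float,
    real: pd.DataFrame,
    mock: pd.DataFrame | list[pd.DataFrame],
    m_step: float = 0.1,
    r_step: float = 0.01,
    m_max: float | None = None,
    r_min: float = 0.0,
    mock_pseudocount: float = 1.0,
    envelope: bool = True,
) -> CutoffSelection | None:
    """Scan the (M, R) cutoff grid for the pair maximizing real hits at
    the target FDR.

    The grid spans M in [0, max observed M] at ``m_step`` resolution and
    R in [``r_min``, 1] at ``r_step``; ties resolve to the larger M
    cutoff, then the larger R cutoff.  ``r_min`` defaults to 0: calling
    a translocation asserts positively correlated replicate shifts,
    which is what the R score measures (pass -1 to search the full
    range).  Returns None when no pair achieves the target.

    Because quadrant hit counts are maximal at the loosest cutoffs, the
    scan always lands on the admissibility frontier, where the empirical
    estimate is noisiest; three safeguards keep the realized error rate
    near the target.  First, mock hits are counted on the real
    experiment's M scale via :func:`mock_equivalent_m` (when ``p_cubed``
    columns are present), removing the BH-rank offset between datasets;
    passing several mock score tables (e.g. all pairings from
    :func:`mock_mr_tables`) averages their counts and shrinks the
    estimator's variance.  Second, with ``envelope`` on, a cutoff pair
    is admissible only if every nested sub-quadrant containing real hits
    also meets the target: a region is not FDR-controlled if its own
    core fails the estimate.  Third, the selected pair itself must meet
    the target with ``mock_pseudocount`` added to the mock hit count
    (the +1 guard of permutation-based FDR estimation).  The returned
    ``fdr`` is the plain, unguarded estimate at the selected pair.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must be in (0, 1)")
    mocks = [mock] if isinstance(mock, pd.DataFrame) else list(mock)
    if m_max is None:
        finite = real["m_score"][np.isfinite(real["m_score"])]
        m_max = float(finite.max()) if len(finite) else 0.0
    m_grid = np.arange(0.0, m_max + m_step, m_step)
    r_grid = np.arange(r_min, 1.0 + r_step, r_step)

    def _suffix_counts(df: pd.DataFrame, m_values: np.ndarray | None = None) -> np.ndarray:
        m = m_values if m_values is not None else df["m_score"].to_numpy()
        m_bin = np.searchsorted(m_grid, m, side="right") - 1
        r_bin = np.searchsorted(r_grid, df["r_score"].to_numpy(), side="right") - 1
        ok = (m_bin >= 0) & (r_bin >= 0)
        H = np.zeros((len(m_grid), len(r_grid)))
        np.add.at(H, (m_bin[ok], r_bin[ok]), 1.0)
        return np.cumsum(np.cumsum(H[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]

    def _mock_m(mk: pd.DataFrame) -> np.ndarray:
        if "p_cubed" in real.columns and "p_cubed" in mk.columns:
            return mock_equivalent_m(real, mk)
        return mk["m_score"].to_numpy()

    hits_real = _suffix_counts(real)
    hits_mock = np.mean([_suffix_counts(mk, _mock_m(mk)) for mk in mocks], axis=0)
    n_mock = float(np.mean([len(mk) for mk in mocks]))
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = (hits_mock / n_mock) / (hits_real / len(real))
        fdr_guarded = ((hits_mock + mock_pseudocount) / n_mock) / (hits_real / len(real))
    admissible = (hits_real > 0) & (fdr <= target_fdr)
    if envelope:
        def _suffix_and(ok: np.ndarray) -> np.ndarray:
            return np.cumprod(
                np.cumprod(ok[::-1, ::-1], axis=0), axis=1
            )[::-1, ::-1].astype(bool)

        # every nested sub-quadrant must meet the plain estimate (empty
        # sub-quadrants are vacuous) ...
        env_plain = _suffix_and(admissible | (hits_real == 0))
        # ... and every sub-quadrant large enough to certify the target at
        # all (>= 1/target real hits) must also meet the guarded estimate
        certifiable = hits_real >= 1.0 / target_fdr
        env_guarded = _suffix_and((fdr_guarded <= target_fdr) | ~certifiable)
        admissible &= env_plain & env_guarded
    admissible &= fdr_guarded <= target_fdr
    if not admissible.any():
        return None
    best_hits = hits_real[admissible].max()
    mi, ri = np.nonzero(admissible & (hits_real == best_hits))
    k = np.lexsort((ri, mi))[-1]  # largest m index, then largest r index
    i, j = mi[k], ri[k]
    return CutoffSelection(
        float(m_grid[i]), float(r_grid[j]), int(hits_real[i, j]), float(fdr[i, j])
    )


def round_robin_pairings(n_maps: int) -> list[list[tuple[int, int]]]:
    """All disjoint pairings of an even number of maps (circle method).

    Returns ``n_maps - 1`` rounds; each round pairs every map exactly
    once, and across rounds every pair of maps meets exactly once.
    """
    if n_maps < 2 or n_maps % 2:
        raise ValueError("need an even number (>= 2) of maps")
    teams = list(range(n_maps))
    rounds = []
    for _ in range(n_maps - 1):
        rounds.append([(teams[i], teams[n_maps - 1 - i]) for i in range(n_maps // 2)])
        teams = [teams[0], teams[-1]] + teams[1:-1]
    return rounds


def mock_mr_tables(
    mock_profiles: list["ProfileMatrix"],
    robust: bool = True,
    seed: int = 0,
    df: int | None = None,
) -> list[pd.DataFrame]:
    """MR score tables for every disjoint pairing of the mock maps.

    A mock experiment splits 2k control maps into k control-vs-control
    pairs, but that split is arbitrary; analyzing all 2k-1 disjoint
    pairings and averaging their hit counts (in :func:`select_cutoffs`)
    removes the dependence on the arbitrary choice and reduces the
    variance of the empirical FDR estimate.
    """
    from .profiling import assemble_feature_matrix

    rounds = round_robin_pairings(len(mock_profiles))
    tables = []
    for rnd in rounds:
        c = assemble_feature_matrix([mock_profiles[a] for a, _ in rnd])
        t = assemble_feature_matrix([mock_profiles[b] for _, b in rnd])
        tables.append(compute_mr(c, t, robust=robust, seed=seed, df=df))
    return tables


def pair_mock_maps(mock_profiles: list[ProfileMatrix]) -> tuple[list[ProfileMatrix], list[ProfileMatrix]]:
    """Split an even number of mock control maps into control-vs-control pairs.

    Maps are paired consecutively: (1,2), (3,4), ...; the first of each
    pair plays "control", the second "treated".
    """
    if len(mock_profiles) < 2 or len(mock_profiles) % 2:
        raise ValueError("mock analysis needs an even number (>= 2) of control maps")
    return mock_profiles[0::2], mock_profiles[1::2]


@dataclass
class MRAnalysis:
    """Bundled outcome of a full dynamic-maps comparison."""

    scores: pd.DataFrame  # real-experiment MR table, plus mover flags
    mock_scores: list[pd.DataFrame]
    selection: CutoffSelection | None
    target_fdr: float

    @property
    def movers(self) -> pd.Series:
        return self.scores["is_mover"]

    @property
    def n_movers(self) -> int:
        return int(self.scores["is_mover"].sum())


def run_mr_analysis(
    control: list[ProfileMatrix],
    treated: list[ProfileMatrix],
    mock: list[ProfileMatrix],
    target_fdr: float = 0.1,
    robust: bool = True,
    seed: int = 0,
    df: int | None = None,
) -> MRAnalysis:
    """Complete MR test: scores, mock-based cutoff selection, mover calls.

    ``control``/``treated`` are matched single-map profile lists (pair r
    of the comparison); ``mock`` is an even number of control-only maps
    used for empirical FDR control via all disjoint pairings.  When no
    cutoff pair achieves the target FDR, no protein is flagged.
    """
    from .profiling import assemble_feature_matrix

    real = compute_mr(
        assemble_feature_matrix(list(control)),
        assemble_feature_matrix(list(treated)),
        robust=robust,
        seed=seed,
        df=df,
    )
    mocks = mock_mr_tables(list(mock), robust=robust, seed=seed, df=df)
    sel = select_cutoffs(target_fdr, real, mocks)
    scores = real.copy()
    if sel is None:
        scores["is_mover"] = False
    else:
        scores["is_mover"] = flag_movers(real, sel.m_cut, sel.r_cut)
    return MRAnalysis(scores, mocks, sel, target_fdr)


def reclassify_after_movement(
    control: ProfileMatrix,
    treated: ProfileMatrix,
    markers: MarkerTable,
    movers: list[str],
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Compartment assignment before and after treatment, movers excluded
    from training.

    Detected movers are removed from the marker set (their control-state
    annotation no longer holds in the treated condition); separate SVMs
    are then trained on the control and treated maps and every shared
    protein's predicted compartment and score are reported for both
    conditions.
    """
    from .classification import predict_all, train_and_crossvalidate

    mover_set = set(movers)
    unknown = mover_set - set(control.protein_ids) - set(treated.protein_ids)
    if unknown:
        warnings.warn(f"mover list references unknown proteins: {sorted(unknown)}")

    def _filtered_markers(pm: ProfileMatrix) -> MarkerTable:
        ann = marker_assignments(pm, markers)
        ann = ann[ann.notna() & ~ann.index.isin(mover_set)]
        return MarkerTable(
            pd.Series(ann.to_numpy(), index=pd.Index(ann.index, name="identifier")),
            markers.label_set,
        )

    fit_c = train_and_crossvalidate(control, _filtered_markers(control), folds, seed)
    fit_t = train_and_crossvalidate(treated, _filtered_markers(treated), folds, seed)
    res_c = predict_all(fit_c.model, control, markers)
    res_t = predict_all(fit_t.model, treated, markers)
    shared = res_c.index.intersection(res_t.index)
    out = pd.DataFrame(
        {
            "compartment_before": res_c.loc[shared, "predicted_compartment"],
            "score_before": res_c.loc[shared, "svm_score"],
            "compartment_after": res_t.loc[shared, "predicted_compartment"],
            "score_after": res_t.loc[shared, "svm_score"],
            "is_mover": shared.isin(mover_set),
        },
        index=shared,
    )
    return out


def write_mr_results(
    mr: pd.DataFrame, path, movers: pd.Series | None = None, params: dict | None = None
) -> None:
    out = mr.reset_index().rename(
        columns={"protein_id": "Protein ID", "m_score": "M score", "r_score": "R score"}
    )
    if movers is not None:
        out["Mover"] = movers.reindex(mr.index).to_numpy()
    _write_with_header(out, path, params)
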