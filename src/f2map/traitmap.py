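"""Mendelian segregation tests and single-locus trait mapping.

Provides Yates-corrected chi-square goodness-of-fit tests for observed
segregation ratios, a penetrance-likelihood genome scan for a binary
trait over a genetic map (with virtual positions between bins filled by
flanking-marker genotype probabilities), permutation-derived LOD
thresholds, marker/trait co-segregation coefficients and physical
interval arithmetic.

The scan replaces composite interval mapping: for a fully penetrant
monogenic trait a single-position likelihood-ratio scan carries the same
information without cofactor machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from ._mapfun import kosambi_inverse
from .binmap import GeneticMap
from .genotyping import SYM_AA, SYM_BB, SYM_H, transition_matrix

__all__ = [
    "PHENO_MISSING",
    "InheritanceTest",
    "ScanResult",
    "MarkerAssoc",
    "PhysicalInterval",
    "yates_chisq",
    "locus_scan",
    "permutation_threshold",
    "cosegregation",
    "physical_interval",
    "read_phenotype_table",
]

PHENO_MISSING = -1

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class InheritanceTest:
    """Yates-corrected chi-square test of a two-class segregation ratio."""

    observed: tuple[int, int]
    ratio: tuple[float, float]
    statistic: float
    p_value: float
    df: int = 1

    def fits_ratio(self, alpha: float = 0.05) -> bool:
        return self.p_value > alpha

    @property
    def statistic_2dp(self) -> float:
        return round(self.statistic, 2)


def yates_chisq(observed: tuple[int, int], ratio: tuple[float, float]) -> InheritanceTest:
    """Continuity-corrected chi-square of two observed counts against p:q.

    chi2 = sum over classes of (max(|O - E| - 0.5, 0))^2 / E with E from
    the stated ratio; df = 1.  The correction is clamped at zero so a
    perfect fit reports exactly 0.
    """
    a, b = observed
    p, q = ratio
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("observed counts must be non-negative with a positive total")
    if p <= 0 or q <= 0:
        raise ValueError("ratio terms must be positive")
    total = a + b
    expected = np.array([p, q]) / (p + q) * total
    dev = np.maximum(np.abs(np.array([a, b]) - expected) - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return InheritanceTest(
        observed=(a, b),
        ratio=(p, q),
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, 1)),
    )


@dataclass
class ScanResult:
    """Genome-scan output: per-position LOD plus peak summaries."""

    table: pd.DataFrame  # columns: lg, pos_cm, lod, is_bin, bin_id
    peak_lg: int
    peak_pos_cm: float
    peak_lod: float
    r_squared: float
    support_interval: tuple[int, float, float]  # lg, lo cM, hi cM
    threshold: Optional[float] = None


@dataclass(frozen=True)
class MarkerAssoc:
    """Co-segregation of one marker with a binary trait."""

    coefficient: float  # percent of scored progeny correctly predicted
    n_matching: int
    n_scored: int

    @property
    def fully_cosegregating(self) -> bool:
        return self.n_matching == self.n_scored


@dataclass(frozen=True)
class PhysicalInterval:
    """Physical span between two markers on one scaffold."""

    scaffold: Optional[str]
    start_bp: int
    end_bp: int
    genes: tuple[str, ...] = ()

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def span_kb(self) -> float:
        return round(self.span_bp / 1000.0, 2)


def _group_states(model: str, recessive_state: int) -> tuple[int, ...]:
    """Genotype states forming the 'affected' class under the trait model."""
    if model == "recessive":
        return (recessive_state,)
    if model == "dominant":
        return (recessive_state, SYM_H)
    raise ValueError(f"unknown model {model!r}")


def _lg_scan_positions(
    lg, bins_by_id, n_progeny: int, step_cm: Optional[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scan positions for one LG and genotype posteriors at each.

    Returns (positions cM, posteriors (P, N, 3), bin id per position with
    -1 for virtual positions).  Observed bin genotypes act as (nearly)
    exact emissions; virtual positions and missing entries are
    uninformative, so posteriors there come from the flanking bins via
    the F2 transition kernel.
    """
    bin_pos = np.asarray(lg.positions_cm, dtype=float)
    if step_cm is not None and lg.length_cm > 0:
        grid = np.arange(0.0, lg.length_cm, step_cm)
        virtual = grid[np.min(np.abs(grid[:, None] - bin_pos[None, :]), axis=1) > 1e-9]
        positions = np.sort(np.concatenate([bin_pos, virtual]))
    else:
        positions = bin_pos.copy()
    bin_of = np.full(len(positions), -1, dtype=int)
    for b_id, p in zip(lg.bin_ids, bin_pos):
        k = int(np.argmin(np.abs(positions - p)))
        bin_of[k] = b_id

    n_pos = len(positions)
    emis = np.ones((n_pos, n_progeny, 3))
    for k in range(n_pos):
        if bin_of[k] < 0:
            continue
        vec = bins_by_id[bin_of[k]].vector
        observed = vec <= SYM_BB
        onehot = np.full((n_progeny, 3), 1e-9)
        onehot[observed, vec[observed].astype(int)] = 1.0
        onehot[~observed] = 1.0
        emis[k] = onehot

    init = np.array([0.25, 0.5, 0.25])
    rs = kosambi_inverse(np.diff(positions)) if n_pos > 1 else np.empty(0)
    trans = [transition_matrix(float(r)) for r in rs]
    alpha = np.empty((n_pos, n_progeny, 3))
    a = init[None, :] * emis[0]
    alpha[0] = a / a.sum(axis=1, keepdims=True)
    for t in range(1, n_pos):
        a = (alpha[t - 1] @ trans[t - 1]) * emis[t]
        s = a.sum(axis=1, keepdims=True)
        alpha[t] = a / np.where(s > 0, s, 1.0)
    beta = np.empty((n_pos, n_progeny, 3))
    beta[-1] = 1.0
    for t in range(n_pos - 2, -1, -1):
        b = (emis[t + 1] * beta[t + 1]) @ trans[t].T
        s = b.sum(axis=1, keepdims=True)
        beta[t] = b / np.where(s > 0, s, 1.0)
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return positions, post, bin_of


def _mixture_lod(
    q: np.ndarray, Y: np.ndarray, max_iter: int = 50, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOD of the two-group penetrance model for each phenotype row.

    ``q[i]`` is the probability progeny i belongs to the affected genotype
    class; ``Y`` is (rows, progeny) of 0/1 phenotypes.  The model fits
    separate phenotype frequencies for the two classes (EM over the
    latent class when q is fractional); the null fits a single frequency.

    Returns (lod, pi_affected, pi_other) per row.
    """
    eps = 1e-9
    Y = np.atleast_2d(Y).astype(float)
    n = Y.shape[1]
    ybar = Y.mean(axis=1)
    ll0 = xlogy(Y, np.clip(ybar[:, None], eps, 1 - eps)).sum(1) + xlogy(
        1 - Y, np.clip(1 - ybar[:, None], eps, 1 - eps)
    ).sum(1)
    sq = q.sum()
    if sq < eps or sq > n - eps:
        return np.zeros(len(Y)), ybar, ybar
    pi_a = np.clip((Y @ q) / sq, eps, 1 - eps)
    pi_b = np.clip((Y @ (1 - q)) / (n - sq), eps, 1 - eps)
    qr = q[None, :]
    for _ in range(max_iter):
        num1 = qr * pi_a[:, None]
        den1 = num1 + (1 - qr) * pi_b[:, None]
        num0 = qr * (1 - pi_a)[:, None]
        den0 = num0 + (1 - qr) * (1 - pi_b)[:, None]
        W = np.where(Y == 1, num1 / np.clip(den1, eps, None), num0 / np.clip(den0, eps, None))
        wsum = np.clip(W.sum(1), eps, None)
        cwsum = np.clip((1 - W).sum(1), eps, None)
        pi_a_new = np.clip((W * Y).sum(1) / wsum, eps, 1 - eps)
        pi_b_new = np.clip(((1 - W) * Y).sum(1) / cwsum, eps, 1 - eps)
        delta = max(np.abs(pi_a_new - pi_a).max(), np.abs(pi_b_new - pi_b).max())
        pi_a, pi_b = pi_a_new, pi_b_new
        if delta < tol:
            break
    m = qr * pi_a[:, None] + (1 - qr) * pi_b[:, None]
    ll1 = (xlogy(Y, m) + xlogy(1 - Y, 1 - m)).sum(1)
    lod = np.clip((ll1 - ll0) / _LN10, 0.0, None)
    return lod, pi_a, pi_b


def _scan_inputs(
    gmap: GeneticMap, model: str, recessive_state: int, step_cm: Optional[float], n_progeny: int
):
    """Per-LG (positions, q matrix, bin ids) for the configured trait model."""
    group_states = _group_states(model, recessive_state)
    bins_by_id = {b.bin_id: b for b in gmap.bins}
    out = []
    for lg in gmap.groups:
        positions, post, bin_of = _lg_scan_positions(lg, bins_by_id, n_progeny, step_cm)
        q = post[:, :, list(group_states)].sum(axis=2)
        out.append((lg.lg_id, positions, q, bin_of))
    return out


def locus_scan(
    gmap: GeneticMap,
    phenotype: np.ndarray,
    model: str = "recessive",
    recessive_state: int = SYM_AA,
    step_cm: Optional[float] = 2.0,
    lod_drop: float = 1.0,
) -> ScanResult:
    """Scan the map for association with a binary phenotype.

    ``phenotype`` is 0/1 per progeny (order matching the genotype matrix
    columns) with -1 for missing; missing-phenotype progeny are excluded.
    LOD compares the two-class penetrance likelihood with the single-
    frequency null; R^2 is computed at the peak on the 0/1 phenotype; the
    support interval is the contiguous run of positions around the peak
    within ``lod_drop`` of it.
    """
    phenotype = np.asarray(phenotype)
    scored = phenotype != PHENO_MISSING
    y = phenotype[scored].astype(float)
    per_lg = _scan_inputs(gmap, model, recessive_state, step_cm, len(phenotype))

    rows = []
    best = None  # (lod, lg_idx, pos_idx, pi_a, pi_b, q)
    for lg_idx, (lg_id, positions, q_all, bin_of) in enumerate(per_lg):
        for k in range(len(positions)):
            q = q_all[k][scored]
            lod, pi_a, pi_b = _mixture_lod(q, y[None, :])
            lod = float(lod[0])
            rows.append(
                {
                    "lg": lg_id,
                    "pos_cm": float(positions[k]),
                    "lod": lod,
                    "is_bin": bin_of[k] >= 0,
                    "bin_id": int(bin_of[k]),
                }
            )
            if best is None or lod > best[0]:
                best = (lod, lg_idx, k, float(pi_a[0]), float(pi_b[0]), q)
    table = pd.DataFrame(rows)

    peak_lod, lg_idx, k, pi_a, pi_b, q_peak = best
    lg_id, positions, _, _ = per_lg[lg_idx]
    fitted = q_peak * pi_a + (1 - q_peak) * pi_b
    rss_null = float(((y - y.mean()) ** 2).sum())
    rss_model = float(((y - fitted) ** 2).sum())
    r_squared = 1.0 - rss_model / rss_null if rss_null > 0 else 0.0

    lg_rows = table[table["lg"] == lg_id].reset_index(drop=True)
    in_drop = (lg_rows["lod"] >= peak_lod - lod_drop).to_numpy()
    peak_row = int(np.argmin(np.abs(lg_rows["pos_cm"].to_numpy() - positions[k])))
    lo = peak_row
    while lo > 0 and in_drop[lo - 1]:
        lo -= 1
    hi = peak_row
    while hi < len(in_drop) - 1 and in_drop[hi + 1]:
        hi += 1
    support = (lg_id, float(lg_rows["pos_cm"][lo]), float(lg_rows["pos_cm"][hi]))

    return ScanResult(
        table=table,
        peak_lg=lg_id,
        peak_pos_cm=float(positions[k]),
        peak_lod=peak_lod,
        r_squared=r_squared,
        support_interval=support,
    )


def permutation_threshold(
    gmap: GeneticMap,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    model: str = "recessive",
    recessive_state: int = SYM_AA,
    step_cm: Optional[float] = 2.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Returns the ``1 - alpha`` quantile of the per-permutation maximum LOD
    over all scan positions; deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    phenotype = np.asarray(phenotype)
    scored = phenotype != PHENO_MISSING
    y = phenotype[scored].astype(float)
    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    per_lg = _scan_inputs(gmap, model, recessive_state, step_cm, len(phenotype))
    max_lod = np.zeros(n_perm)
    for _, positions, q_all, _ in per_lg:
        for k in range(len(positions)):
            lod, _, _ = _mixture_lod(q_all[k][scored], Y)
            np.maximum(max_lod, lod, out=max_lod)
    return float(np.quantile(max_lod, 1.0 - alpha))


def cosegregation(
    populations: Sequence[tuple[np.ndarray, np.ndarray]],
    model: str = "recessive",
    recessive_state: int = SYM_AA,
) -> MarkerAssoc:
    """Percent of progeny whose marker genotype predicts their phenotype.

    ``populations`` is one or more (marker genotype vector, phenotype
    vector) pairs, pooled.  Under the recessive model the predicted
    phenotype is affected (1) iff the genotype is the recessive homozygote
    class; progeny with a missing genotype or phenotype are not scored.
    """
    group_states = _group_states(model, recessive_state)
    n_match = n_scored = 0
    for genotypes, phenotype in populations:
        genotypes = np.asarray(genotypes)
        phenotype = np.asarray(phenotype)
        if genotypes.shape != phenotype.shape:
            raise ValueError("genotype and phenotype vectors must align")
        scored = (genotypes <= SYM_BB) & (phenotype != PHENO_MISSING)
        predicted = np.isin(genotypes[scored], group_states).astype(int)
        n_scored += int(scored.sum())
        n_match += int((predicted == phenotype[scored]).sum())
    if n_scored == 0:
        raise ValueError("no scored progeny")
    return MarkerAssoc(
        coefficient=round(100.0 * n_match / n_scored, 1),
        n_matching=n_match,
        n_scored=n_scored,
    )


def physical_interval(
    start_bp: int,
    end_bp: int,
    scaffold: Optional[str] = None,
    scaffold_b: Optional[str] = None,
    annotation: Optional[pd.DataFrame] = None,
) -> PhysicalInterval:
    """Physical span between two marker coordinates.

    Both markers must lie on the same scaffold (pass ``scaffold`` and
    ``scaffold_b`` to assert this).  ``annotation`` is an optional frame
    with columns gene, scaffold, start, end; genes overlapping the span
    are reported.
    """
    if scaffold_b is not None and scaffold is not None and scaffold != scaffold_b:
        raise ValueError(
            f"markers on different scaffolds ({scaffold} vs {scaffold_b}); interval undefined"
        )
    lo, hi = min(start_bp, end_bp), max(start_bp, end_bp)
    genes: tuple[str, ...] = ()
    if annotation is not None and len(annotation):
        sel = annotation
        if scaffold is not None:
            sel = sel[sel["scaffold"] == scaffold]
        overlap = (sel["start"] <= hi) & (sel["end"] >= lo)
        genes = tuple(sel[overlap]["gene"].astype(str))
    return PhysicalInterval(scaffold=scaffold, start_bp=lo, end_bp=hi, genes=genes)


def read_phenotype_table(path, progeny: Sequence[str]) -> np.ndarray:
    """Read a (sample, phenotype) TSV into a 0/1/-1 vector ordered like ``progeny``."""
    df = pd.read_csv(path, sep="\t")
    mapping = {"indeterminate": 0, "determinate": 1}
    values = {
        str(row["sample"]): mapping.get(str(row["phenotype"]).lower(), PHENO_MISSING)
        for _, row in df.iterrows()
    }
    return np.array([values.get(p, PHENO_MISSING) for p in progeny], dtype=np.int8)
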