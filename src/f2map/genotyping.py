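"""Six-symbol genotype coding and HMM-based error correction.

Each progeny call at a parent-unique locus is coded into the alphabet
{AA, BB, H, C, D, -}: AA/BB are confident homozygous calls for the P1/P2
allele (depth >= threshold), D/C their low-depth counterparts, H any
heterozygous call and '-' a missing call.  A three-state (AA/H/BB) hidden
Markov model along each scaffold then replaces the low-confidence C/D/-
symbols with posterior-decoded states and removes isolated miscalls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mapfun import kosambi_inverse

__all__ = [
    "SYM_AA",
    "SYM_H",
    "SYM_BB",
    "SYM_C",
    "SYM_D",
    "SYM_MISS",
    "SYMBOLS",
    "HmmParams",
    "GenotypeMatrix",
    "code_genotype",
    "build_matrix",
    "transition_matrix",
    "hmm_correct",
    "posterior_matrix",
    "genotype_accuracy",
    "write_matrix",
    "write_corrected",
]

# Coded-symbol integer codes. The first three double as corrected-state codes.
SYM_AA, SYM_H, SYM_BB, SYM_C, SYM_D, SYM_MISS = 0, 1, 2, 3, 4, 5
SYMBOLS = np.array(["AA", "H", "BB", "C", "D", "-"])

# observation classes used by the HMM emission model
_OBS_HOM_P1, _OBS_HET, _OBS_HOM_P2, _OBS_NONE = 0, 1, 2, 3
# coded symbol -> observation class
_SYM_TO_OBS = np.array(
    [_OBS_HOM_P1, _OBS_HET, _OBS_HOM_P2, _OBS_HOM_P2, _OBS_HOM_P1, _OBS_NONE]
)


@dataclass
class HmmParams:
    """Parameters of the correction HMM.

    ``error`` is the per-read miscall probability, ``cm_per_mb`` converts
    physical to genetic distance before the inverse-Kosambi transform, and
    symbols are only rewritten when the winning posterior clears
    ``posterior_threshold``.
    """

    error: float = 0.005
    cm_per_mb: float = 1.0
    posterior_threshold: float = 0.95
    initial: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def validate(self) -> "HmmParams":
        if not 0.0 < self.error < 0.5:
            raise ValueError("error must lie in (0, 0.5)")
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must lie in (0.5, 1]")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")
        if abs(sum(self.initial) - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        return self


@dataclass
class GenotypeMatrix:
    """Coded genotypes for all parent-unique loci x progeny.

    ``symbols`` and ``depths`` are loci x progeny arrays; loci are sorted
    by (scaffold, position) and strictly increasing within each scaffold.
    """

    loci: pd.DataFrame  # scaffold, pos, origin
    progeny: list[str]
    symbols: np.ndarray  # int8, codes into SYMBOLS
    depths: np.ndarray  # int32
    depth_threshold: int = 5

    def __post_init__(self):
        if self.symbols.shape != (len(self.loci), len(self.progeny)):
            raise ValueError("symbol matrix shape does not match loci x progeny")
        for _, pos in self.loci.groupby("scaffold", sort=False)["pos"]:
            if not pos.is_monotonic_increasing or pos.duplicated().any():
                raise ValueError("locus positions must be strictly increasing per scaffold")


def code_genotype(origin: str, call: str | None, depth: int, threshold: int = 5) -> str:
    """Code one observation into the six-symbol alphabet.

    ``call`` names the allele content relative to the parents
    (``hom_p1`` / ``hom_p2`` / ``het``) or is None for no call.
    """
    if origin not in ("P1", "P2"):
        raise ValueError(f"origin must be P1 or P2, got {origin!r}")
    if call is None or call == "none":
        return "-"
    if call == "het":
        return "H"
    if call == "hom_p1":
        return "AA" if depth >= threshold else "D"
    if call == "hom_p2":
        return "BB" if depth >= threshold else "C"
    raise ValueError(f"unknown call {call!r}")


def build_matrix(
    table: pd.DataFrame,
    origins: pd.DataFrame,
    depth_threshold: int = 5,
    include_indels: bool = False,
    p1: str = "P1",
    p2: str = "P2",
) -> GenotypeMatrix:
    """Code a merged locus table into a :class:`GenotypeMatrix`.

    Only loci classified P1-/P2-unique are kept; InDel loci are dropped
    unless ``include_indels`` is set (the map is an SNP map).  Progeny are
    all samples except the two parents.
    """
    from .variants import is_indel, sample_names

    merged = table.merge(origins[["scaffold", "pos", "origin"]], on=["scaffold", "pos"])
    keep = merged["origin"].isin(["P1", "P2"])
    if not include_indels:
        keep &= ~is_indel(merged)
    merged = merged[keep].reset_index(drop=True)
    merged = merged.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)
    progeny = [s for s in sample_names(table) if s not in (p1, p2)]

    n_loci, n_prog = len(merged), len(progeny)
    symbols = np.full((n_loci, n_prog), SYM_MISS, dtype=np.int8)
    depths = np.zeros((n_loci, n_prog), dtype=np.int32)
    p1_is_alt = (merged["origin"] == "P1").to_numpy()
    for j, s in enumerate(progeny):
        gt = merged[f"gt:{s}"].to_numpy(dtype=object)
        dp = merged[f"dp:{s}"].fillna(0).to_numpy(dtype=np.int32)
        depths[:, j] = dp
        het = gt == "het"
        hom_alt = gt == "hom_alt"
        hom_ref = gt == "hom_ref"
        hom_p1 = (hom_alt & p1_is_alt) | (hom_ref & ~p1_is_alt)
        hom_p2 = (hom_alt & ~p1_is_alt) | (hom_ref & p1_is_alt)
        deep = dp >= depth_threshold
        symbols[het, j] = SYM_H
        symbols[hom_p1 & deep, j] = SYM_AA
        symbols[hom_p1 & ~deep, j] = SYM_D
        symbols[hom_p2 & deep, j] = SYM_BB
        symbols[hom_p2 & ~deep, j] = SYM_C
    return GenotypeMatrix(
        loci=merged[["scaffold", "pos", "origin"]].copy(),
        progeny=progeny,
        symbols=symbols,
        depths=depths,
        depth_threshold=depth_threshold,
    )


def transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition matrix for recombination fraction ``r``.

    Rows/columns are (AA, H, BB); each row sums to 1.  ``r = 0`` gives the
    identity and ``r = 0.5`` the stationary 1:2:1 mixing kernel.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def _emissions(symbols: np.ndarray, depths: np.ndarray, error: float) -> np.ndarray:
    """Per-locus emission probabilities, shape (L, N, 3).

    Binomial read model: a read drawn from state AA/H/BB shows the P2
    allele with probability error / 0.5 / 1-error; a homozygous-looking
    call means all reads agreed, a het call that both alleles were seen.
    Missing observations are uninformative (emission 1 in every state).
    """
    obs = _SYM_TO_OBS[symbols]
    d = depths.astype(float)
    p = np.array([error, 0.5, 1.0 - error])  # P(read shows P2 allele | state)
    e = np.ones(symbols.shape + (3,))
    for s in range(3):
        all_p1 = (1.0 - p[s]) ** d
        all_p2 = p[s] ** d
        het = np.clip(1.0 - all_p1 - all_p2, 1e-12, None)
        e[..., s] = np.where(
            obs == _OBS_HOM_P1,
            np.clip(all_p1, 1e-300, None),
            np.where(obs == _OBS_HOM_P2, np.clip(all_p2, 1e-300, None), 1.0),
        )
        e[obs == _OBS_HET, s] = het[obs == _OBS_HET]
    return e


def posterior_matrix(matrix: GenotypeMatrix, params: HmmParams) -> np.ndarray:
    """Forward-backward posteriors over (AA, H, BB), shape (L, N, 3).

    Computed independently per progeny within each scaffold; inter-locus
    recombination fractions come from the inverse Kosambi transform of
    ``cm_per_mb`` x physical distance.
    """
    params.validate()
    L, N = matrix.symbols.shape
    post = np.zeros((L, N, 3))
    emis = _emissions(matrix.symbols, matrix.depths, params.error)
    init = np.asarray(params.initial)
    positions = matrix.loci["pos"].to_numpy()
    for _, idx in matrix.loci.groupby("scaffold", sort=False).indices.items():
        pos = positions[idx]
        d_cm = params.cm_per_mb * np.diff(pos) / 1e6
        rs = kosambi_inverse(d_cm)
        e = emis[idx]  # (l, N, 3)
        n_l = len(idx)
        trans = [transition_matrix(float(r)) for r in np.atleast_1d(rs)]
        # scaled forward
        alpha = np.empty((n_l, N, 3))
        a = init[None, :] * e[0]
        alpha[0] = a / a.sum(axis=1, keepdims=True)
        for t in range(1, n_l):
            a = (alpha[t - 1] @ trans[t - 1]) * e[t]
            alpha[t] = a / a.sum(axis=1, keepdims=True)
        # scaled backward
        beta = np.empty((n_l, N, 3))
        beta[-1] = 1.0
        for t in range(n_l - 2, -1, -1):
            b = (e[t + 1] * beta[t + 1]) @ trans[t].T
            beta[t] = b / b.sum(axis=1, keepdims=True)
        g = alpha * beta
        post[idx] = g / g.sum(axis=2, keepdims=True)
    return post


def hmm_correct(matrix: GenotypeMatrix, params: HmmParams | None = None) -> np.ndarray:
    """Correct a coded matrix into states {AA, H, BB, missing}.

    Low-confidence symbols (C, D, '-') become the posterior argmax state
    when its probability clears ``posterior_threshold`` and stay missing
    otherwise.  High-confidence symbols (AA, H, BB) are flipped only when
    their own posterior support falls below ``1 - posterior_threshold``,
    which removes isolated single-locus miscalls without erasing genuine
    double recombinants.
    """
    params = (params or HmmParams()).validate()
    post = posterior_matrix(matrix, params)
    argmax = post.argmax(axis=2).astype(np.int8)
    pmax = post.max(axis=2)
    sym = matrix.symbols
    corrected = np.full(sym.shape, SYM_MISS, dtype=np.int8)

    low_conf = (sym == SYM_C) | (sym == SYM_D) | (sym == SYM_MISS)
    confident = pmax >= params.posterior_threshold
    corrected[low_conf & confident] = argmax[low_conf & confident]

    high_conf = ~low_conf
    own = np.take_along_axis(post, sym.clip(max=2)[..., None].astype(np.int64), axis=2)[..., 0]
    flip = high_conf & (own < 1.0 - params.posterior_threshold)
    corrected[high_conf] = sym[high_conf]
    corrected[flip] = argmax[flip]
    return corrected


def genotype_accuracy(corrected: np.ndarray, truth_states: np.ndarray) -> float:
    """Fraction of non-missing corrected entries that match the truth."""
    if corrected.shape != truth_states.shape:
        raise ValueError("corrected and truth matrices must have the same shape")
    scored = corrected != SYM_MISS
    if not scored.any():
        raise ValueError("no non-missing entries to score")
    return float((corrected[scored] == truth_states[scored]).mean())


def write_matrix(path, matrix: GenotypeMatrix) -> None:
    """Write a coded matrix as TSV (rows: scaffold:pos, columns: progeny)."""
    df = pd.DataFrame(
        SYMBOLS[matrix.symbols],
        columns=matrix.progeny,
        index=matrix.loci["scaffold"].astype(str) + ":" + matrix.loci["pos"].astype(str),
    )
    df.rename_axis("locus").to_csv(path, sep="\t")


def write_corrected(path, matrix: GenotypeMatrix, corrected: np.ndarray) -> None:
    """Write a corrected state matrix as TSV with NA for missing."""
    labels = np.array(["AA", "H", "BB", "", "", "NA"])
    df = pd.DataFrame(
        labels[corrected],
        columns=matrix.progeny,
        index=matrix.loci["scaffold"].astype(str) + ":" + matrix.loci["pos"].astype(str),
    )
    df.rename_axis("locus").to_csv(path, sep="\t")
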