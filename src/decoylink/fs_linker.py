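"""Built-in Fellegi-Sunter test-bed linker.

Record pairs are compared variable-by-variable into agree / disagree /
missing indicators.  A two-class conditional-independence mixture (the
classical Fellegi-Sunter model) is fitted by EM on the comparison patterns:
``m_k`` is the probability of agreement on variable ``k`` for a true link,
``u_k`` for a non-link, and ``lambda`` the prevalence of links among
compared pairs.  Posterior linkage scores

    d_ij = lam * P(pattern | link) / [lam * P(pattern|link) + (1-lam) * P(pattern|non-link)]

are thresholded at ``xi in [0.5, 1)`` and deduplicated to a one-to-one link
set by greedy descending-score assignment.

Any external linkage engine can replace this module by returning a
:class:`ScoredPairs` for a pair of files; downstream estimation depends only
on that contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import RecordTable

_EPS = 1e-10


@dataclass
class ComparisonSet:
    """Agreement patterns for all cross-file pairs (within blocks if any).

    ``codes`` encodes, per pair, the per-variable state in base 3:
    0 = disagree, 1 = agree, 2 = missing (a missing value on either side).
    """

    i: np.ndarray
    j: np.ndarray
    codes: np.ndarray
    variables: list[str]
    n_a: int
    n_b: int

    @property
    def n_pairs(self) -> int:
        return len(self.codes)

    def patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique pattern codes, their counts, and the inverse index."""
        uniq, inverse, counts = np.unique(
            self.codes, return_inverse=True, return_counts=True
        )
        return uniq, counts, inverse


def _decode(uniq: np.ndarray, n_vars: int) -> np.ndarray:
    """(n_patterns, n_vars) array of trits 0/1/2."""
    out = np.empty((len(uniq), n_vars), dtype=np.int8)
    rem = uniq.astype(np.int64)
    for k in range(n_vars):
        out[:, k] = rem % 3
        rem //= 3
    return out


def build_comparisons(
    A: RecordTable,
    B_aug: RecordTable,
    variables: list[str] | None = None,
    block_on: str | None = None,
) -> ComparisonSet:
    """Binary agreement comparisons for every cross-file pair.

    With ``block_on``, only pairs sharing the blocking value are compared.
    A comparison involving a missing value on either side is marked missing.
    """
    variables = list(variables or A.variables)
    for v in variables:
        if v not in A.data.columns or v not in B_aug.data.columns:
            raise ValueError(f"variable {v!r} absent from one of the tables")
    if block_on is not None:
        for t, nm in ((A, "A"), (B_aug, "B")):
            if block_on not in t.data.columns:
                raise ValueError(f"blocking variable {block_on!r} absent from file {nm}")

    # shared categorical codes so equality is comparable across files
    a_codes = np.empty((A.n, len(variables)), dtype=np.int64)
    b_codes = np.empty((B_aug.n, len(variables)), dtype=np.int64)
    for k, v in enumerate(variables):
        both = pd.concat([A.data[v], B_aug.data[v]], ignore_index=True)
        codes = pd.factorize(both, use_na_sentinel=True)[0]
        a_codes[:, k] = codes[: A.n]
        b_codes[:, k] = codes[A.n:]

    if block_on is None:
        ia = np.arange(A.n)
        jb = np.arange(B_aug.n)
        blocks = [(ia, jb)]
    else:
        a_blk = A.data[block_on]
        b_blk = B_aug.data[block_on]
        blocks = []
        for val in pd.unique(a_blk.dropna()):
            ia = np.flatnonzero((a_blk == val).to_numpy())
            jb = np.flatnonzero((b_blk == val).to_numpy())
            if len(ia) and len(jb):
                blocks.append((ia, jb))

    i_parts, j_parts, c_parts = [], [], []
    powers = 3 ** np.arange(len(variables), dtype=np.int64)
    for ia, jb in blocks:
        ii = np.repeat(ia, len(jb)).astype(np.int64)
        jj = np.tile(jb, len(ia)).astype(np.int64)
        code = np.zeros(len(ii), dtype=np.int64)
        for k in range(len(variables)):
            av = a_codes[ia, k][:, None]
            bv = b_codes[jb, k][None, :]
            miss = (av < 0) | (bv < 0)
            agree = (av == bv) & ~miss
            trit = agree.astype(np.int64) + 2 * miss.astype(np.int64)
            code += powers[k] * trit.ravel()
        i_parts.append(ii)
        j_parts.append(jj)
        c_parts.append(code)
    if not i_parts:
        raise ValueError("no comparable pairs (empty blocks)")
    return ComparisonSet(
        i=np.concatenate(i_parts),
        j=np.concatenate(j_parts),
        codes=np.concatenate(c_parts),
        variables=variables,
        n_a=A.n,
        n_b=B_aug.n,
    )


@dataclass
class FSParams:
    """Fellegi-Sunter mixture parameters."""

    m: np.ndarray          # P(agree on var k | link)
    u: np.ndarray          # P(agree on var k | non-link)
    lam: float             # P(link) among compared pairs
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False


def _pattern_likelihoods(
    trits: np.ndarray, m: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern P(pattern | link) and P(pattern | non-link).

    Missing components contribute no factor (conditioning on the observed
    comparison components).
    """
    agree = trits == 1
    disagree = trits == 0
    log_pm = agree @ np.log(m) + disagree @ np.log1p(-m)
    log_pu = agree @ np.log(u) + disagree @ np.log1p(-u)
    return np.exp(log_pm), np.exp(log_pu)


def em_fit(
    comparisons: ComparisonSet,
    init: FSParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FSParams:
    """Fit the two-class conditional-independence mixture by EM.

    The observed-data log-likelihood is non-decreasing across iterations;
    fitting stops when its change falls below ``tol``.  A label-switching
    guard swaps the classes if agreement turns out likelier under the
    non-link class.
    """
    uniq, counts, _ = comparisons.patterns()
    n_vars = len(comparisons.variables)
    if comparisons.n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if len(uniq) < 2:
        raise ValueError("degenerate comparison data")
    trits = _decode(uniq, n_vars)
    agree = (trits == 1).astype(float)
    observed = (trits != 2).astype(float)
    w = counts.astype(float)
    n_pairs = w.sum()

    if init is not None:
        m = np.asarray(init.m, dtype=float).copy()
        u = np.asarray(init.u, dtype=float).copy()
        lam = float(init.lam)
    else:
        obs_tot = w @ observed
        u = (w[:, None] * agree * observed).sum(axis=0) / np.maximum(obs_tot, 1.0)
        m = np.full(n_vars, 0.9)
        # expected links bounded by the smaller file: lam0 ~ n_A / n_pairs
        lam = min(0.1, comparisons.n_a / n_pairs)
    m = np.clip(m, _EPS, 1 - _EPS)
    u = np.clip(u, _EPS, 1 - _EPS)
    lam = float(np.clip(lam, _EPS, 1 - _EPS))

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pm, pu = _pattern_likelihoods(trits, m, u)
        mix = lam * pm + (1 - lam) * pu
        ll = float(w @ np.log(np.maximum(mix, 1e-300)))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        r = lam * pm / mix
        wm = w * r
        wu = w * (1 - r)
        lam = float(np.clip(wm.sum() / n_pairs, _EPS, 1 - _EPS))
        m = (wm @ (agree * observed)) / np.maximum(wm @ observed, _EPS)
        u = (wu @ (agree * observed)) / np.maximum(wu @ observed, _EPS)
        m = np.clip(m, _EPS, 1 - _EPS)
        u = np.clip(u, _EPS, 1 - _EPS)

    if m.sum() < u.sum():  # label-switching guard: links agree more
        m, u = u, m
        lam = 1 - lam
    return FSParams(m=m, u=u, lam=lam, loglik_trace=trace, converged=converged)


@dataclass
class ScoredPairs:
    """Candidate pairs with posterior linkage scores in [0, 1]."""

    i: np.ndarray
    j: np.ndarray
    score: np.ndarray
    is_synthetic_j: np.ndarray

    def __len__(self) -> int:
        return len(self.score)

    def real_scores(self) -> np.ndarray:
        return self.score[~self.is_synthetic_j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.i,
                "j": self.j,
                "score": self.score,
                "is_synthetic_j": self.is_synthetic_j.astype(int),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ScoredPairs":
        df = pd.read_csv(path)
        return cls(
            i=df["i"].to_numpy(np.int64),
            j=df["j"].to_numpy(np.int64),
            score=df["score"].to_numpy(float),
            is_synthetic_j=df["is_synthetic_j"].to_numpy(bool),
        )


def posterior_scores(
    params: FSParams,
    comparisons: ComparisonSet,
    is_synthetic_j: np.ndarray | None = None,
) -> ScoredPairs:
    """Posterior link probability per pair under conditional independence."""
    uniq, _, inverse = comparisons.patterns()
    trits = _decode(uniq, len(comparisons.variables))
    pm, pu = _pattern_likelihoods(
        trits, np.clip(params.m, _EPS, 1 - _EPS), np.clip(params.u, _EPS, 1 - _EPS)
    )
    d_pattern = params.lam * pm / (params.lam * pm + (1 - params.lam) * pu)
    score = d_pattern[inverse]
    if is_synthetic_j is None:
        synth = np.zeros(comparisons.n_pairs, dtype=bool)
    else:
        synth = np.asarray(is_synthetic_j, dtype=bool)[comparisons.j]
    return ScoredPairs(
        i=comparisons.i.copy(), j=comparisons.j.copy(), score=score, is_synthetic_j=synth
    )


def link_set(scores: ScoredPairs, xi: float) -> np.ndarray:
    """One-to-one link set D(xi): pairs with score above xi, deduplicated.

    Pairs with ``d_ij > xi`` are taken greedily in descending score order
    (ties by lower i, then lower j); each record index is used at most once.
    Returns an ``(n_links, 2)`` integer array of (i, j).
    """
    if not (0.5 <= xi < 1):
        raise ValueError(
            "xi must lie in [0.5, 1): setting the lower bound for xi at 0.5 "
            "guarantees coherent one-to-one links"
        )
    keep = np.flatnonzero(scores.score > xi)
    if len(keep) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = keep[np.lexsort((scores.j[keep], scores.i[keep], -scores.score[keep]))]
    used_i: set[int] = set()
    used_j: set[int] = set()
    out = []
    for k in order:
        i, j = int(scores.i[k]), int(scores.j[k])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        out.append((i, j))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class FellegiSunterLinker:
    """The pluggable linker contract, backed by the built-in FS mixture.

    Calling the linker on files ``(A, B_aug)`` returns :class:`ScoredPairs`;
    any external engine exposing the same callable signature can stand in.
    """

    max_iter: int = 500
    tol: float = 1e-6

    def __call__(
        self,
        A: RecordTable,
        B_aug: RecordTable,
        variables: list[str] | None = None,
        block_on: str | None = None,
        seed: int = 0,
    ) -> ScoredPairs:
        comp = build_comparisons(A, B_aug, variables=variables, block_on=block_on)
        params = em_fit(comp, max_iter=self.max_iter, tol=self.tol, seed=seed)
        return posterior_scores(params, comp, is_synthetic_j=B_aug.is_synthetic)
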