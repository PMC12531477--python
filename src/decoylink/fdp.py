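"""Decoy-based estimation of the false discovery proportion in record linkage.

The larger file B is augmented with decoy records sampled from its estimated
empirical distribution.  Decoys cannot truly link to any real entity, so any
declared link whose B-side member is a decoy is a known false positive.  With
``FPsynth`` the number of such decoy links and ``N_real_linked`` the number of
declared links among real pairs, the estimator of the FDP of the real-data
linkage is

    FDP_hat(xi) = FPsynth(xi) * (N_B / N_synth) / N_real_linked(xi)

which is unbiased when (i) decoys represent records of B that do not form a
link and (ii) decoys minimally perturb the linkage.  The classical augmented
variant FDP_hat_synth = FPsynth * (1 + N_B/N_synth) / N_all_linked and the
naive model-based estimate probFDP_hat = sum(1 - d_ij)/#retained (over
retained real pairs) are computed for comparison; both are biased for the
real-data FDP.

An estimate above one is impossible for a proportion and flags a violation of
condition (i) — decoys resembling links more than non-links do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .records import RecordTable
from .synthesizer import SynthModel, fit_synthesizer, sample_synthetic

logger = logging.getLogger(__name__)

DEFAULT_XI_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def augment_file(
    B: RecordTable,
    synth_model: SynthModel | None = None,
    alpha: float = 0.10,
    seed: int = 0,
    block_on: str | None = None,
    smoothing: float = 0.5,
) -> RecordTable:
    """Concatenate B with ``round(alpha * N_B)`` decoys flagged SYNTH.

    Decoys are interleaved at seeded-random row positions rather than
    appended, so that linkers resolving score ties by record position cannot
    systematically favour real records over decoys; provenance is carried by
    the ``source`` column, not by position.

    With ``block_on``, the decoy budget is split per block and each block's
    decoys are sampled from a model fitted to that block only (a fresh model
    is always fitted per block in that case).
    """
    if not (0 < alpha <= 0.2):
        raise ValueError("alpha must lie in (0, 0.2]")
    if B.n == 0:
        raise ValueError("file B is empty")
    rng = np.random.default_rng(seed)
    if block_on is None:
        n_synth = round(alpha * B.n)
        if n_synth == 0:
            raise ValueError("synthetic set empty: round(alpha * N_B) = 0")
        model = synth_model or fit_synthesizer(B, smoothing=smoothing)
        synth = sample_synthetic(model, n_synth, seed=int(rng.integers(2**31)))
        return _interleave(B.concat(synth), rng)

    if block_on not in B.data.columns:
        raise ValueError(f"blocking variable {block_on!r} absent from B")
    parts = [B]
    offset = 0
    for val in pd.unique(B.data[block_on].dropna()):
        blk = B.subset((B.data[block_on] == val).to_numpy())
        n_synth = round(alpha * blk.n)
        if n_synth == 0:
            continue
        model = fit_synthesizer(blk, smoothing=smoothing)
        synth = sample_synthetic(model, n_synth, seed=int(rng.integers(2**31)))
        df = synth.data.copy()
        df["block"] = val
        df["record_id"] = [f"SYN{offset + r}" for r in range(n_synth)]
        offset += n_synth
        parts.append(RecordTable(df, synth.variables))
    if offset == 0:
        raise ValueError("synthetic set empty: round(alpha * N_block) = 0 in every block")
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    return _interleave(out, rng)


def _interleave(table: RecordTable, rng: np.random.Generator) -> RecordTable:
    perm = rng.permutation(table.n)
    return RecordTable(table.data.iloc[perm].reset_index(drop=True), table.variables)


def count_decoy_links(
    D: np.ndarray, is_synthetic: np.ndarray
) -> tuple[int, int]:
    """Split a link set into decoy links and real links by B-side provenance.

    ``is_synthetic`` is indexed by the j (B-side) position of the augmented
    file.  Returns ``(fp_synth, n_real_linked)``.
    """
    D = np.asarray(D, dtype=np.int64).reshape(-1, 2)
    is_synthetic = np.asarray(is_synthetic, dtype=bool)
    if len(D) == 0:
        return 0, 0
    j = D[:, 1]
    if j.min() < 0 or j.max() >= len(is_synthetic):
        raise ValueError("link set contains a j index with unknown provenance")
    fp_synth = int(is_synthetic[j].sum())
    return fp_synth, int(len(D) - fp_synth)


def estimate_fdp(fp_synth: int, n_real_linked: int, n_B: int, n_synth: int) -> float:
    """The decoy-count estimator FPsynth * (N_B / N_synth) / N_real_linked."""
    _check_counts(fp_synth, n_real_linked, n_B, n_synth)
    if n_real_linked == 0:
        return 0.0 if fp_synth == 0 else math.inf
    return fp_synth * (n_B / n_synth) / n_real_linked


def estimate_fdp_augmented(
    fp_synth: int, n_all_linked: int, n_B: int, n_synth: int
) -> float:
    """The augmented-data variant FPsynth * (1 + N_B/N_synth) / N_all_linked.

    Reported for comparison only: it targets the FDP of the augmented task
    and is biased for the real-data FDP.
    """
    _check_counts(fp_synth, n_all_linked, n_B, n_synth)
    if n_all_linked == 0:
        return 0.0 if fp_synth == 0 else math.inf
    return fp_synth * (1 + n_B / n_synth) / n_all_linked


def _check_counts(a: int, b: int, n_B: int, n_synth: int) -> None:
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if n_B < 1 or n_synth < 1:
        raise ValueError("n_B and n_synth must be positive")


def prob_fdp(real_scores: np.ndarray, xi: float) -> float:
    """Naive model-based estimate: mean of (1 - d_ij) over retained real pairs."""
    d = np.asarray(real_scores, dtype=float)
    kept = d[d > xi]
    if len(kept) == 0:
        return 0.0
    return float(np.mean(1.0 - kept))


@dataclass
class FDPEstimate:
    """Estimator output at one threshold for one repetition."""

    xi: float
    fp_synth: int
    n_real_linked: int
    n_all_linked: int
    n_B: int
    n_synth: int
    fdp_hat: float
    fdp_hat_synth: float
    prob_fdp_hat: float | None = None
    links: np.ndarray | None = None

    @property
    def exceeds_one(self) -> bool:
        return self.fdp_hat > 1

    @classmethod
    def from_counts(
        cls,
        xi: float,
        fp_synth: int,
        n_real_linked: int,
        n_B: int,
        n_synth: int,
        prob_fdp_hat: float | None = None,
        links: np.ndarray | None = None,
    ) -> "FDPEstimate":
        n_all = n_real_linked + fp_synth
        return cls(
            xi=xi,
            fp_synth=fp_synth,
            n_real_linked=n_real_linked,
            n_all_linked=n_all,
            n_B=n_B,
            n_synth=n_synth,
            fdp_hat=estimate_fdp(fp_synth, n_real_linked, n_B, n_synth),
            fdp_hat_synth=estimate_fdp_augmented(fp_synth, n_all, n_B, n_synth),
            prob_fdp_hat=prob_fdp_hat,
            links=links,
        )


def check_conditions(
    estimate: FDPEstimate,
    n_A: int | None = None,
    fp_real: int | None = None,
) -> dict:
    """Diagnostics for the estimator's validity conditions.

    Always reports whether the decoy-link proportion exceeds the real-link
    proportion (equivalently ``fdp_hat > 1``), which flags bias.  With ground
    truth (``fp_real`` = the true number of real false positives and ``n_A``
    the size of file A), also reports the signed difference between the decoy
    FP proportion and the real FP proportion and its order of magnitude.
    """
    out = {
        "exceeds_one": estimate.exceeds_one,
        "proportion_inequality_ok": not estimate.exceeds_one,
    }
    if fp_real is not None and n_A is not None:
        diff = estimate.fp_synth / (n_A * estimate.n_synth) - fp_real / (
            n_A * estimate.n_B
        )
        out["condition_diff"] = diff
        out["condition_magnitude"] = (
            -math.inf if diff == 0 else math.floor(math.log10(abs(diff)))
        )
    return out


@dataclass
class FDPCurve:
    """Per-threshold estimates across repetitions of the decoy procedure."""

    xi_grid: list[float]
    replicates: list[list[FDPEstimate]]  # [repetition][xi index]
    n_B: int
    alpha: float
    seed: int

    @property
    def repetitions(self) -> int:
        return len(self.replicates)

    def estimates_at(self, xi: float) -> list[FDPEstimate]:
        k = self.xi_grid.index(xi)
        return [rep[k] for rep in self.replicates]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, rep in enumerate(self.replicates):
            for est in rep:
                rows.append(
                    {
                        "repetition": r,
                        "xi": est.xi,
                        "fp_synth": est.fp_synth,
                        "n_real_linked": est.n_real_linked,
                        "n_all_linked": est.n_all_linked,
                        "n_synth": est.n_synth,
                        "fdp_hat": est.fdp_hat,
                        "fdp_hat_synth": est.fdp_hat_synth,
                        "prob_fdp_hat": est.prob_fdp_hat,
                        "exceeds_one": est.exceeds_one,
                    }
                )
        return pd.DataFrame(rows)


def run_procedure(
    A: RecordTable,
    B: RecordTable,
    linker: Callable,
    alpha: float = 0.10,
    xi_grid: Sequence[float] = DEFAULT_XI_GRID,
    repetitions: int = 10,
    seed: int = 0,
    block_on: str | None = None,
    smoothing: float = 0.5,
    keep_links: bool = False,
) -> FDPCurve:
    """Run the full decoy procedure: synthesize, link, count, estimate.

    Each repetition refits the synthesizer on B, draws a fresh decoy set with
    a repetition-specific seed, links A against the augmented file with the
    supplied linker (linker seed held fixed, so synthesis is the only source
    of randomness), and computes an :class:`FDPEstimate` per grid threshold.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    xi_grid = [float(x) for x in xi_grid]
    if any(not (0.5 <= x < 1) for x in xi_grid):
        raise ValueError("xi grid must lie within [0.5, 1)")
    from .fs_linker import link_set  # local import to avoid cycle

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(repetitions + 1) & 0x7FFFFFFF]
    linker_seed = rep_seeds[-1]
    replicates: list[list[FDPEstimate]] = []
    for r in range(repetitions):
        try:
            B_aug = augment_file(
                B, alpha=alpha, seed=rep_seeds[r], block_on=block_on, smoothing=smoothing
            )
            scored = linker(A, B_aug, variables=A.variables, block_on=block_on, seed=linker_seed)
            is_synth = B_aug.is_synthetic
            n_synth = int(is_synth.sum())
            real_d = scored.real_scores()
            rep_out = []
            for xi in xi_grid:
                D = link_set(scored, xi)
                fp_synth, n_real = count_decoy_links(D, is_synth)
                rep_out.append(
                    FDPEstimate.from_counts(
                        xi=xi,
                        fp_synth=fp_synth,
                        n_real_linked=n_real,
                        n_B=B.n,
                        n_synth=n_synth,
                        prob_fdp_hat=prob_fdp(real_d, xi),
                        links=D if keep_links else None,
                    )
                )
        except Exception as exc:  # annotate with the repetition index
            raise RuntimeError(f"procedure repetition {r} failed: {exc}") from exc
        logger.info(
            "repetition %d: %s",
            r,
            "; ".join(
                f"xi={e.xi:.2f} FPsynth={e.fp_synth} Nreal_linked={e.n_real_linked}"
                for e in rep_out
            ),
        )
        replicates.append(rep_out)
    return FDPCurve(
        xi_grid=xi_grid, replicates=replicates, n_B=B.n, alpha=alpha, seed=seed
    )


TRUNCATED_MEAN = "truncated_mean"
CAPPED_MEAN = "capped_mean"
MEDIAN = "median"


def aggregate(curve: FDPCurve, method: str = CAPPED_MEAN) -> pd.DataFrame:
    """Aggregate per-threshold replicate estimates into a point estimate + SE.

    ``truncated_mean`` drops replicates exceeding one (error if all dropped),
    ``capped_mean`` averages ``min(estimate, 1)``, ``median`` takes the sample
    median.  The standard error is the sample SD of the aggregated inputs
    divided by sqrt(#used); a single replicate reports SE 0.
    """
    rows = []
    for k, xi in enumerate(curve.xi_grid):
        ests = [rep[k] for rep in curve.replicates]
        vals = np.array([e.fdp_hat for e in ests], dtype=float)
        if method == TRUNCATED_MEAN:
            used = vals[vals <= 1]
            if len(used) == 0:
                raise ValueError("all estimates exceed one -- bias suspected")
        elif method == CAPPED_MEAN:
            used = np.minimum(vals, 1.0)
        elif method == MEDIAN:
            used = vals
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
        point = float(np.median(used)) if method == MEDIAN else float(np.mean(used))
        se = float(np.std(used, ddof=1) / np.sqrt(len(used))) if len(used) > 1 else 0.0
        if method == MEDIAN and np.isinf(se):
            se = math.inf
        rows.append(
            {
                "xi": xi,
                "estimate": point,
                "se": se,
                "n_used": int(len(used)),
                "n_exceeding_one": int(sum(e.exceeds_one for e in ests)),
                "mean_links": float(np.mean([e.n_real_linked for e in ests])),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TuneResult:
    achieved: bool
    xi: float | None = None
    links_retained: float | None = None


def tune_threshold(aggregated: pd.DataFrame, target_fdp: float) -> TuneResult:
    """Smallest grid threshold whose aggregate estimate meets the target FDP.

    Returns an explicit not-achievable result when no grid point qualifies:
    in that case neither the linkage nor downstream inference is reliable.
    """
    ok = aggregated[aggregated["estimate"] <= target_fdp].sort_values("xi")
    if len(ok) == 0:
        return TuneResult(achieved=False)
    row = ok.iloc[0]
    return TuneResult(achieved=True, xi=float(row["xi"]), links_retained=float(row["mean_links"]))
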