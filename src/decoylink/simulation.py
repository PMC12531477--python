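"""Synthetic linkage problems with known ground truth.

Generates two overlapping files of records described by a handful of
categorical linkage variables, with configurable overlap (fraction of the
smaller file forming links), discrimination level (proportion of unique
variable combinations), link mechanism (uniform at random, or dependent on
the variables through a logistic selection score), per-variable miscoding
errors, and duplicated records.  Ground truth (the set of true links) is
returned alongside the files so linkage output and FDP estimates can be
scored exactly.

Variable distributions are multinomials with heterogeneous cardinalities and
geometric-decay category probabilities; cardinalities are rescaled by a
calibration search until the expected proportion of unique combinations in
the larger file matches the requested discrimination level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fdp import FDPEstimate, augment_file, check_conditions, count_decoy_links, prob_fdp
from .fs_linker import FellegiSunterLinker, link_set
from .records import SOURCE_A, SOURCE_B, RecordTable
from .synthesizer import classifier_auc, synth_quality_auc

AT_RANDOM = "at_random"
DEPENDS_ON_VARIABLES = "depends_on_variables"

_BASE_CARDINALITIES = (2, 6, 12, 30, 60)


@dataclass
class SimulationConfig:
    n_a: int = 2000
    n_b: int = 5000
    overlap: float = 0.5
    n_vars: int = 5
    target_discrimination: float = 0.95
    link_mechanism: str = AT_RANDOM
    dependence_weights: tuple | None = None
    error_rate: float = 0.02
    duplicate_rate_link: float = 0.0
    duplicate_rate_nonlink: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.overlap <= 1):
            raise ValueError("overlap must lie in (0, 1]")
        if self.n_a > self.n_b:
            raise ValueError("file A must be the smaller file (n_a <= n_b)")
        for r in (self.error_rate, self.duplicate_rate_link, self.duplicate_rate_nonlink):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.link_mechanism not in (AT_RANDOM, DEPENDS_ON_VARIABLES):
            raise ValueError(f"unknown link mechanism {self.link_mechanism!r}")

    @property
    def variables(self) -> list[str]:
        return [f"V{k+1}" for k in range(self.n_vars)]


@dataclass
class SimulationTruth:
    """The set of true links plus enough bookkeeping to score a linkage."""

    links: set  # {(a_record_id, b_record_id)}
    a_record_ids: list
    b_record_ids: list
    linked_b_ids: set
    n_links: int
    config: SimulationConfig | None = None


def _category_probs(k: int) -> np.ndarray:
    """Geometric-decay category probabilities over k categories."""
    p = np.exp(-3.0 * np.arange(k) / k)
    return p / p.sum()


def _cardinalities(n_vars: int, scale: float) -> list[int]:
    base = [_BASE_CARDINALITIES[k % len(_BASE_CARDINALITIES)] for k in range(n_vars)]
    return [max(2, int(round(b * scale))) for b in base]


def _expected_unique_fraction(cards: list[int], n: int, u: np.ndarray) -> float:
    """Monte-Carlo expectation of the singleton proportion among n records.

    For a record X drawn from the product-multinomial, the chance it is
    unique among n draws is (1 - p(X))^(n-1); common uniform draws ``u``
    (shape m x n_vars) keep the estimate smooth in the cardinality scale.
    """
    log_px = np.zeros(u.shape[0])
    for k, K in enumerate(cards):
        p = _category_probs(K)
        idx = np.searchsorted(np.cumsum(p), u[:, k], side="right")
        idx = np.minimum(idx, K - 1)
        log_px += np.log(p[idx])
    return float(np.mean(np.exp((n - 1) * np.log1p(-np.minimum(np.exp(log_px), 1 - 1e-12)))))


def _calibrate_scale(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    u = rng.random((20000, config.n_vars))
    lo, hi = 0.02, 80.0
    f_lo = _expected_unique_fraction(_cardinalities(config.n_vars, lo), config.n_b, u)
    f_hi = _expected_unique_fraction(_cardinalities(config.n_vars, hi), config.n_b, u)
    target = config.target_discrimination
    if not (f_lo - 0.02 <= target <= f_hi + 0.02):
        raise ValueError(
            f"target discrimination {target} unreachable with {config.n_vars} "
            f"variables at n={config.n_b}: achievable range is "
            f"[{f_lo:.3f}, {f_hi:.3f}]"
        )
    for _ in range(40):
        mid = math.sqrt(lo * hi)
        f_mid = _expected_unique_fraction(_cardinalities(config.n_vars, mid), config.n_b, u)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return _cardinalities(config.n_vars, math.sqrt(lo * hi))


def simulate_files(
    config: SimulationConfig,
) -> tuple[RecordTable, RecordTable, SimulationTruth]:
    """Draw two overlapping files and their ground-truth link set.

    An entity population of ``n_a + n_b - n_links`` individuals is drawn
    from the calibrated variable distributions; ``n_links = round(overlap *
    n_a)`` entities appear in both files (chosen uniformly under
    ``at_random``, or proportional to a logistic score of the variables
    under ``depends_on_variables``).  Miscoding resamples a value from its
    marginal independently per file; duplicates are appended last as copies
    with fresh record ids, marked as non-links in the truth.
    """
    rng = np.random.default_rng(config.seed)
    cards = _calibrate_scale(config, rng)
    probs = [_category_probs(K) for K in cards]

    n_links = round(config.overlap * config.n_a)
    n_entities = config.n_a + config.n_b - n_links
    values = np.column_stack(
        [rng.choice(len(p), size=n_entities, p=p) for p in probs]
    )

    if config.link_mechanism == AT_RANDOM:
        linked = rng.choice(n_entities, size=n_links, replace=False)
    else:
        w = np.asarray(
            config.dependence_weights
            if config.dependence_weights is not None
            else np.ones(config.n_vars),
            dtype=float,
        )
        score = np.zeros(n_entities)
        for k, p in enumerate(probs):
            idx = np.arange(len(p))
            mu = float(idx @ p)
            sd = float(np.sqrt(((idx - mu) ** 2) @ p))
            score += w[k] * (values[:, k] - mu) / max(sd, 1e-12)
        # Gumbel top-k == weighted sampling without replacement prop. to exp(score)
        keys = score + rng.gumbel(size=n_entities)
        linked = np.argsort(-keys)[:n_links]

    rest = np.setdiff1d(np.arange(n_entities), linked, assume_unique=False)
    rest = rng.permutation(rest)
    a_only = rest[: config.n_a - n_links]
    b_only = rest[config.n_a - n_links:]
    a_entities = np.concatenate([linked, a_only]).astype(int)
    b_entities = np.concatenate([linked, b_only]).astype(int)

    def build(entities: np.ndarray, prefix: str, source: str) -> pd.DataFrame:
        vals = values[entities].copy()
        if config.error_rate > 0:
            for k, p in enumerate(probs):
                mask = rng.random(len(entities)) < config.error_rate
                vals[mask, k] = rng.choice(len(p), size=int(mask.sum()), p=p)
        df = pd.DataFrame(vals, columns=config.variables)
        df["record_id"] = [f"{prefix}{e}" for e in entities]
        df["entity_id"] = entities
        df["source"] = source
        return df

    a_df = build(a_entities, "A", SOURCE_A)
    b_df = build(b_entities, "B", SOURCE_B)
    links = {(f"A{e}", f"B{e}") for e in linked}
    linked_set = set(int(e) for e in linked)

    def duplicate(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        n = len(df)
        is_link = df["entity_id"].isin(linked_set).to_numpy()
        parts = [df]
        c = 0
        for rate, mask in (
            (config.duplicate_rate_link, is_link),
            (config.duplicate_rate_nonlink, ~is_link),
        ):
            n_dup = round(rate * n)
            if n_dup == 0:
                continue
            pool = np.flatnonzero(mask)
            pick = rng.choice(pool, size=n_dup, replace=n_dup > len(pool))
            dup = df.iloc[pick].copy()
            dup["record_id"] = [f"{prefix}_dup{c + t}" for t in range(n_dup)]
            c += n_dup
            parts.append(dup)
        return pd.concat(parts, ignore_index=True)

    if config.duplicate_rate_link or config.duplicate_rate_nonlink:
        a_df = duplicate(a_df, "A")
        b_df = duplicate(b_df, "B")

    a_df = a_df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    b_df = b_df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    A = RecordTable(a_df, config.variables)
    B = RecordTable(b_df, config.variables)
    truth = SimulationTruth(
        links=links,
        a_record_ids=list(a_df["record_id"]),
        b_record_ids=list(b_df["record_id"]),
        linked_b_ids={b for _, b in links},
        n_links=n_links,
        config=config,
    )
    return A, B, truth


def measure_discrimination(table: RecordTable) -> float:
    """Proportion of records whose linkage-variable combination is unique."""
    if table.n == 0:
        raise ValueError("empty table")
    counts = table.values.value_counts(dropna=False)
    singles = int((counts == 1).sum())
    return singles / table.n


def evaluate_linkage(
    D: np.ndarray, truth: SimulationTruth, A: RecordTable, B_aug: RecordTable
) -> dict:
    """Score a link set against ground truth.

    Pairs whose B-side member is synthetic are tallied separately as
    ``fp_synth`` and excluded from TP/FP.  The FDP of an empty link set is
    defined as 0; sensitivity is TP / #true links.
    """
    D = np.asarray(D, dtype=np.int64).reshape(-1, 2)
    a_ids = A.record_ids.to_numpy()
    b_ids = B_aug.record_ids.to_numpy()
    synth = B_aug.is_synthetic
    tp = fp = fp_synth = 0
    for i, j in D:
        if synth[j]:
            fp_synth += 1
        elif (a_ids[i], b_ids[j]) in truth.links:
            tp += 1
        else:
            fp += 1
    n_real = tp + fp
    return {
        "TP": tp,
        "FP": fp,
        "FN": truth.n_links - tp,
        "fp_synth": fp_synth,
        "fdp": fp / n_real if n_real else 0.0,
        "sensitivity": tp / truth.n_links if truth.n_links else 0.0,
    }


def auc_link(
    B: RecordTable, truth: SimulationTruth, folds: int = 5, seed: int = 0
) -> float:
    """AUC of a classifier separating B-records that form a link from those
    that do not; ~0.5 under links-at-random."""
    real = B.subset(~B.is_synthetic)
    y = real.record_ids.isin(truth.linked_b_ids).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both linked and non-linked records are required")
    return classifier_auc(real.values, y, folds=folds, seed=seed)


def bias_study(
    config: SimulationConfig,
    linker=None,
    alpha: float = 0.10,
    xi: float = 0.5,
    n_reps: int = 10,
    seed: int = 0,
    compute_aucs: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated end-to-end evaluation of the decoy procedure.

    Each repetition simulates a fresh linkage problem, runs one full decoy
    procedure (synthesize, augment, link, count) at threshold ``xi``, and
    records the true FDP, the bias of the decoy and naive estimators, the
    condition-magnitude diagnostic, and the synthesis / link AUCs.  Returns
    the per-repetition table and a mean/SD summary.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    linker = linker or FellegiSunterLinker()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_reps) & 0x7FFFFFFF
    rows = []
    for r in range(n_reps):
        cfg = SimulationConfig(**{**config.__dict__, "seed": int(seeds[2 * r])})
        A, B, truth = simulate_files(cfg)
        B_aug = augment_file(B, alpha=alpha, seed=int(seeds[2 * r + 1]))
        scored = linker(A, B_aug, variables=A.variables, seed=0)
        D = link_set(scored, xi)
        fp_synth, n_real = count_decoy_links(D, B_aug.is_synthetic)
        est = FDPEstimate.from_counts(
            xi=xi,
            fp_synth=fp_synth,
            n_real_linked=n_real,
            n_B=B.n,
            n_synth=int(B_aug.is_synthetic.sum()),
            prob_fdp_hat=prob_fdp(scored.real_scores(), xi),
        )
        metrics = evaluate_linkage(D, truth, A, B_aug)
        cond = check_conditions(est, n_A=A.n, fp_real=metrics["FP"])
        row = {
            "repetition": r,
            "true_fdp": metrics["fdp"],
            "fdp_hat": est.fdp_hat,
            "fdp_hat_bias": est.fdp_hat - metrics["fdp"],
            "prob_fdp_hat": est.prob_fdp_hat,
            "prob_fdp_bias": est.prob_fdp_hat - metrics["fdp"],
            "condition_magnitude": cond.get("condition_magnitude"),
            "sensitivity": metrics["sensitivity"],
            "n_real_linked": n_real,
            "fp_synth": fp_synth,
            "exceeds_one": est.exceeds_one,
        }
        if compute_aucs:
            decoys = B_aug.subset(B_aug.is_synthetic)
            row["auc_synth"] = synth_quality_auc(B, decoys, seed=int(seeds[2 * r + 1]))
            row["auc_link"] = auc_link(B, truth, seed=int(seeds[2 * r + 1]))
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["repetition"]).select_dtypes("number")
    summary = pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})
    return table, summary


# ---------------------------------------------------------------------------
# Outcome data-generating process for the inference demonstration
# ---------------------------------------------------------------------------


@dataclass
class OutcomeDGP:
    """Bimodal linear outcome: Y = -5 + X1 + X2 + 20*X3 + eps with
    X1 ~ N(0,1), X2 ~ N(0, 3), X3 ~ Beta(0.2, 0.1) - 2/3, eps ~ N(0, noise)."""

    intercept: float = -5.0
    beta: tuple = (1.0, 1.0, 20.0)
    x2_scale: float = 3.0
    beta_a: float = 0.2
    beta_b: float = 0.1
    noise_scale: float = 1.0


def sample_outcome_dgp(
    n: int, dgp: OutcomeDGP | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw (X1, X2, X3, Y) for n correctly linked pairs."""
    dgp = dgp or OutcomeDGP()
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = dgp.x2_scale * rng.standard_normal(n)
    x3 = rng.beta(dgp.beta_a, dgp.beta_b, size=n) - 2.0 / 3.0
    eps = dgp.noise_scale * rng.standard_normal(n)
    y = dgp.intercept + dgp.beta[0] * x1 + dgp.beta[1] * x2 + dgp.beta[2] * x3 + eps
    return pd.DataFrame({"X1": x1, "X2": x2, "X3": x3, "Y": y})


def simulate_outcome(
    truth: SimulationTruth, dgp: OutcomeDGP | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Attach covariates (file A side) and outcomes (file B side) to a truth.

    Linked pairs get covariates and the linear outcome from the DGP;
    non-linked B-records receive an outcome drawn by inverse-transform
    sampling from the empirical CDF of the linked outcomes, so linked and
    non-linked outcomes share a marginal distribution.
    """
    if truth.n_links == 0:
        raise ValueError("truth contains no links")
    dgp = dgp or OutcomeDGP()
    rng = np.random.default_rng(seed)
    pairs = sorted(truth.links)
    linked = sample_outcome_dgp(len(pairs), dgp, seed=int(rng.integers(2**31)))
    linked["a_record_id"] = [a for a, _ in pairs]
    linked["b_record_id"] = [b for _, b in pairs]

    linked_b = {b for _, b in pairs}
    other_b = [b for b in truth.b_record_ids if b not in linked_b]
    y_sorted = np.sort(linked["Y"].to_numpy())
    u = rng.random(len(other_b))
    # right-continuous ECDF inverse; ties resolve toward the smaller outcome
    idx = np.minimum((u * len(y_sorted)).astype(int), len(y_sorted) - 1)
    nonlinked = pd.Series(y_sorted[idx], index=pd.Index(other_b, name="b_record_id"), name="Y")
    return linked, nonlinked


def fit_links_ols(linked: pd.DataFrame):
    """OLS of Y on (X1, X2, X3) with intercept; returns the fitted results."""
    import statsmodels.api as sm

    X = sm.add_constant(linked[["X1", "X2", "X3"]])
    return sm.OLS(linked["Y"], X).fit()
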