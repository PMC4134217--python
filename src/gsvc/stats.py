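"""Performance metrics and permutation tests for comparing classifiers.

Comparing cross-validated accuracies with a Student t test is unsound because
fold scores are neither independent nor normal, so two non-parametric tests are
provided:

* ``test1`` — a paired sign-permutation test on per-unit accuracy differences
  between two methods: the null distribution is built by randomly flipping the
  sign of each paired difference (exhaustively when 2^n is affordable).
* ``test2`` — a randomized ANOVA comparing accuracy *curves* of several methods
  over a shared hyper-parameter grid (e.g. the number of parcels q): the
  statistic is the ANOVA F for the method main effect with the grid as a
  blocking factor, and the null is built by permuting the method assignment
  within each (grid value, fold) cell.

Both tests are two-sided with the add-one correction on randomly sampled
permutations, and are exactly reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n_permutations: int
    test_name: str


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions amongst all attempted predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean(y_true == y_pred))


def test1_paired_sign(scores_a, scores_b, n_perm: int = 10_000,
                      seed: int = 0) -> ComparisonResult:
    """Paired sign-permutation test of equal performance of two methods.

    ``scores_a`` and ``scores_b`` are per-unit (e.g. per-dataset or per-fold)
    accuracies of the two methods on the same units.  The statistic is the mean
    paired difference; under the null each difference's sign is exchangeable.
    Enumeration is exhaustive when 2^n <= n_perm, giving an exact test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("scores must be paired 1-d arrays of length >= 2")
    diffs = a - b
    observed = float(diffs.mean())
    n = len(diffs)
    if np.all(diffs == 0):
        return ComparisonResult(0.0, 1.0, 0, "test1")
    if 2 ** n <= n_perm:
        # exhaustive: all sign patterns (the identity is included in the count)
        signs = 1 - 2 * ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
        stats = signs @ diffs / n
        p = float(np.mean(np.abs(stats) >= abs(observed) - 1e-12))
        n_used = 2 ** n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        stats = signs @ diffs / n
        p = float((1 + np.sum(np.abs(stats) >= abs(observed) - 1e-12)) / (n_perm + 1))
        n_used = n_perm
    return ComparisonResult(observed, min(p, 1.0), n_used, "test1")


def _f_method_effect(x: np.ndarray) -> np.ndarray:
    """ANOVA F for the method main effect; x shape (..., m, Q, F).

    Q is treated as a blocking factor.  With fold replicates (F > 1) the error
    term is the within-cell mean square; with F == 1 the method-by-block
    interaction serves as the error term.
    """
    m, Q, F = x.shape[-3:]
    grand = x.mean(axis=(-3, -2, -1), keepdims=True)
    method_mean = x.mean(axis=(-2, -1), keepdims=True)
    block_mean = x.mean(axis=(-3, -1), keepdims=True)
    cell_mean = x.mean(axis=-1, keepdims=True)
    ss_method = (Q * F) * np.sum((method_mean - grand) ** 2, axis=(-3, -2, -1))
    ss_cells = F * np.sum((cell_mean - grand) ** 2, axis=(-3, -2, -1))
    ss_block = (m * F) * np.sum((block_mean - grand) ** 2, axis=(-3, -2, -1))
    if F > 1:
        ss_err = np.sum((x - cell_mean) ** 2, axis=(-3, -2, -1))
        dof_err = m * Q * (F - 1)
    else:
        ss_err = ss_cells - ss_method - ss_block
        dof_err = (m - 1) * (Q - 1)
    ms_method = ss_method / (m - 1)
    ms_err = ss_err / dof_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_method / np.where(ms_err > 0, ms_err, 1.0),
                     np.where(ms_method > 0, np.inf, 0.0))
    return f


def test2_randomized_anova(curves: np.ndarray, n_perm: int = 10_000,
                           seed: int = 0) -> ComparisonResult:
    """Randomized ANOVA comparing performance curves of several methods.

    ``curves`` has shape (n_methods, n_grid, n_folds): for each method, the
    fold accuracies at each shared hyper-parameter value.  The null permutes
    which method each observation belongs to, independently within every
    (grid value, fold) cell, preserving the blocking structure.
    """
    x = np.asarray(curves, dtype=float)
    if x.ndim != 3:
        raise ValueError("curves must be (n_methods, n_grid, n_folds)")
    m, Q, F = x.shape
    if m < 2:
        raise ValueError("need at least two methods to compare")
    observed = float(_f_method_effect(x))
    rng = np.random.default_rng(seed)
    # permutation indices along the method axis, independent per (perm, Q, F) cell
    order = np.argsort(rng.random((n_perm, Q, F, m)), axis=-1)       # (P, Q, F, m)
    xt = np.transpose(x, (1, 2, 0))                                   # (Q, F, m)
    permuted = np.take_along_axis(np.broadcast_to(xt, order.shape), order, axis=-1)
    permuted = np.transpose(permuted, (0, 3, 1, 2))                   # (P, m, Q, F)
    stats = _f_method_effect(permuted)
    p = float((1 + np.sum(stats >= observed - 1e-12)) / (n_perm + 1))
    return ComparisonResult(observed, min(p, 1.0), n_perm, "test2")


def binomial_chance_interval(n_trials: int, chance: float = 0.5,
                             alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation (1 - alpha) interval of accuracy under chance guessing."""
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(chance * (1 - chance) / n_trials)
    return chance - half, chance + half
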