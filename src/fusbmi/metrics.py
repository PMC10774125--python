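"""Performance quantification and chance statistics.

Two headline metrics track decoder performance trial by trial:

* cumulative percent correct = (# correct predictions) / (# predictions);
* cumulative mean angular error = (1/n) * sum |angular error|, for
  eight-target sessions, where the angular error between two of the eight
  directions lies in {0, 45, 90, 135, 180} degrees and a CENTER prediction
  scores 180 degrees (conservative: CENTER is never correct).

Chance envelopes: the accuracy envelope comes from the exact binomial law at
the chance rate 1/n_targets (lower bound: largest k with CDF(k-1) <= alpha;
upper bound: smallest k with CDF(k) >= 1-alpha; "significant" means strictly
beyond the bound).  The angular-error envelope comes from a permutation null
(uniform random directions, 5th/95th quantiles over replicates).  The "last
nonsignificant trial" is the largest evaluated index whose statistic is not
beyond its envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import PERIPHERAL_DIRECTIONS, Direction

__all__ = [
    "angular_error",
    "binomial_envelope",
    "PermutationEnvelope",
    "permutation_envelope",
    "PerformanceTrace",
    "cumulative_trace",
    "confusion_matrix",
    "plot_trace",
]

#: Null distribution of |angular error| for one uniform-random prediction
#: against a uniform cue: P(0)=1/8, P(45)=P(90)=P(135)=2/8, P(180)=1/8.
ANGULAR_ERROR_VALUES = np.array([0.0, 45.0, 90.0, 135.0, 180.0])
ANGULAR_ERROR_PROBS = np.array([1, 2, 2, 2, 1]) / 8.0


def angular_error(cue: Direction, pred: Direction | None) -> float:
    """Minimal absolute angle (degrees) between cue and prediction.

    CENTER or missing predictions score 180 (never correct, maximal error).
    """
    if cue is Direction.CENTER or not cue.is_peripheral:
        raise ValueError("cue must be a peripheral direction")
    if pred is None or pred is Direction.CENTER:
        return 180.0
    d = abs(cue.angle_deg - pred.angle_deg) % 360.0
    return min(d, 360.0 - d)


def binomial_envelope(n: int, p_chance: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial chance envelope for n predictions, as fractions.

    low = (largest k with CDF(k-1) <= alpha) / n;
    high = (smallest k with CDF(k) >= 1-alpha) / n.
    Accuracy strictly above ``high`` is significant at one-sided alpha.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p_chance < 1.0:
        raise ValueError("p_chance must be in (0, 1)")
    dist = stats.binom(n, p_chance)
    # smallest k with cdf(k) >= 1 - alpha
    high_k = int(dist.ppf(1.0 - alpha))
    if dist.cdf(high_k) < 1.0 - alpha:  # guard against ppf edge rounding
        high_k += 1
    # largest j = k-1 with cdf(j) <= alpha
    j = int(dist.ppf(alpha))
    if dist.cdf(j) > alpha:
        j -= 1
    low_k = j + 1
    return low_k / n, high_k / n


@dataclass
class PermutationEnvelope:
    """Permutation null of cumulative mean |angular error| per n predictions."""

    n: np.ndarray  # 1..n_max
    low: np.ndarray  # 5th percentile (alpha quantile)
    high: np.ndarray  # 95th percentile
    null_mean: np.ndarray
    replicates: int
    seed: int | None = None


def permutation_envelope(
    n_max: int,
    n_targets: int = 8,
    replicates: int = 100_000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> PermutationEnvelope:
    """Chance envelope for the cumulative mean angular error.

    For each replicate, n_max uniform-random predictions are scored against
    uniform cues (by symmetry the error distribution is the same as
    conditioning on any cue sequence); the cumulative mean over the first n
    draws gives the null at n, and the alpha/1-alpha quantiles over
    replicates form the envelope.
    """
    if n_targets != 8:
        raise ValueError("the angular-error null is defined for 8-target tasks")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if replicates < 1000:
        import warnings

        warnings.warn("permutation envelope with < 1000 replicates is unstable")
    rng = np.random.default_rng(seed)
    # |angular error| of a uniform prediction vs a uniform cue depends only on
    # the uniform index difference: lookup over the 8 possible separations
    lut = np.array([0, 45, 90, 135, 180, 135, 90, 45], dtype=np.float32)
    idx = rng.integers(0, 8, size=(n_max, replicates), dtype=np.uint8)
    errors = lut[idx]  # (n_max, replicates), rows contiguous
    del idx
    cummean = np.cumsum(errors, axis=0, dtype=np.float32)
    del errors
    cummean /= np.arange(1, n_max + 1, dtype=np.float32)[:, None]
    low = np.quantile(cummean, alpha, axis=1)
    high = np.quantile(cummean, 1.0 - alpha, axis=1)
    null_mean = cummean.mean(axis=1, dtype=np.float64)
    return PermutationEnvelope(
        n=np.arange(1, n_max + 1),
        low=np.asarray(low, dtype=float),
        high=np.asarray(high, dtype=float),
        null_mean=np.asarray(null_mean, dtype=float),
        replicates=replicates,
        seed=seed,
    )


@dataclass
class PerformanceTrace:
    """Per evaluated trial: running accuracy (and, for eight-target sessions,
    running mean angular error) with chance envelopes and the last
    nonsignificant trial index."""

    trial_numbers: np.ndarray  # session trial indices of evaluated trials
    correct: np.ndarray  # bool per evaluated trial
    accuracy: np.ndarray  # cumulative fraction correct
    acc_env_low: np.ndarray
    acc_env_high: np.ndarray
    last_nonsignificant: int | None  # trial number; None if nothing evaluated
    n_targets: int
    alpha: float = 0.05
    angular_errors: np.ndarray | None = None
    mean_angular_error: np.ndarray | None = None
    ang_env_low: np.ndarray | None = None
    ang_env_high: np.ndarray | None = None
    last_nonsignificant_angular: int | None = None

    @property
    def n_evaluated(self) -> int:
        return int(self.trial_numbers.size)

    @property
    def final_accuracy(self) -> float:
        return float(self.accuracy[-1])

    @property
    def final_mean_angular_error(self) -> float | None:
        if self.mean_angular_error is None:
            return None
        return float(self.mean_angular_error[-1])

    def significant_at_end(self) -> bool:
        """Accuracy strictly above the envelope at the last evaluated trial."""
        return bool(self.accuracy[-1] > self.acc_env_high[-1])

    def trials_to_significance(self) -> int | None:
        """Trial number of the first trial after the last nonsignificant one;
        None when the trace never becomes significant."""
        if self.last_nonsignificant is None:
            return None
        if self.last_nonsignificant >= int(self.trial_numbers[-1]):
            return None  # never (stayed nonsignificant through the end)
        later = self.trial_numbers[self.trial_numbers > self.last_nonsignificant]
        return int(later[0]) if later.size else None

    def as_dataframe(self) -> pd.DataFrame:
        data = {
            "trial": self.trial_numbers,
            "correct": self.correct.astype(int),
            "cumulative_accuracy": self.accuracy,
            "env_low": self.acc_env_low,
            "env_high": self.acc_env_high,
        }
        if self.mean_angular_error is not None:
            data["angular_error_deg"] = self.angular_errors
            data["cumulative_mean_angular_error_deg"] = self.mean_angular_error
            data["ang_env_low"] = self.ang_env_low
            data["ang_env_high"] = self.ang_env_high
        return pd.DataFrame(data)


def cumulative_trace(
    predictions: list,
    cues: list,
    n_targets: int,
    trial_numbers: list[int] | None = None,
    alpha: float = 0.05,
    seed: int | None = 0,
    permutation_replicates: int = 100_000,
) -> PerformanceTrace:
    """Running performance with chance envelopes over evaluated trials."""
    if len(predictions) == 0:
        raise ValueError("no evaluated predictions")
    if len(predictions) != len(cues):
        raise ValueError("predictions and cues must align")
    n = len(predictions)
    numbers = np.asarray(trial_numbers if trial_numbers is not None else range(1, n + 1))

    correct = np.array(
        [p is not None and p == c for p, c in zip(predictions, cues)], dtype=bool
    )
    counts = np.arange(1, n + 1)
    accuracy = np.cumsum(correct) / counts

    env = np.array([binomial_envelope(i, 1.0 / n_targets, alpha) for i in counts])
    acc_low, acc_high = env[:, 0], env[:, 1]
    sig_acc = accuracy > acc_high

    ang = mean_ang = ang_low = ang_high = None
    last_nonsig_ang = None
    if n_targets == 8:
        ang = np.array([angular_error(c, p) for p, c in zip(predictions, cues)])
        mean_ang = np.cumsum(ang) / counts
        perm = permutation_envelope(
            n, n_targets=8, replicates=permutation_replicates, alpha=alpha, seed=seed
        )
        ang_low, ang_high = perm.low, perm.high
        sig_ang = mean_ang < ang_low
        nonsig_ang = np.flatnonzero(~sig_ang)
        last_nonsig_ang = int(numbers[nonsig_ang[-1]]) if nonsig_ang.size else 0

    nonsig = np.flatnonzero(~sig_acc)
    last_nonsig = int(numbers[nonsig[-1]]) if nonsig.size else 0

    return PerformanceTrace(
        trial_numbers=numbers,
        correct=correct,
        accuracy=accuracy,
        acc_env_low=acc_low,
        acc_env_high=acc_high,
        last_nonsignificant=last_nonsig,
        n_targets=n_targets,
        alpha=alpha,
        angular_errors=ang,
        mean_angular_error=mean_ang,
        ang_env_low=ang_low,
        ang_env_high=ang_high,
        last_nonsignificant_angular=last_nonsig_ang,
    )


def confusion_matrix(cues: list, predictions: list, n_targets: int = 8) -> pd.DataFrame:
    """Row-normalized percentage confusion matrix (rows = cued class sum to
    100).  Eight-target matrices include a CENTER prediction column; a cued
    class with zero predictions yields a NaN row (flagged, not zeroed)."""
    if n_targets == 2:
        row_classes = [Direction.R, Direction.L]
    else:
        row_classes = list(PERIPHERAL_DIRECTIONS)
    col_classes = list(row_classes)
    if n_targets == 8 or any(p is Direction.CENTER for p in predictions):
        col_classes = col_classes + [Direction.CENTER]

    counts = pd.DataFrame(
        0.0, index=[c.name for c in row_classes], columns=[c.name for c in col_classes]
    )
    for cue, pred in zip(cues, predictions):
        if pred is None:
            continue
        counts.loc[cue.name, pred.name] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals, axis=0) * 100.0  # zero-prediction rows -> NaN
    return pct


def plot_trace(trace: PerformanceTrace, path=None, title: str | None = None):
    """Accuracy-vs-trial plot with the gray chance envelope and a red line at
    the last nonsignificant trial."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = 2 if trace.mean_angular_error is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(7, 3 * n_rows), squeeze=False)
    ax = axes[0][0]
    x = trace.trial_numbers
    ax.fill_between(x, trace.acc_env_low * 100, trace.acc_env_high * 100,
                    color="0.8", label="chance envelope")
    ax.plot(x, trace.accuracy * 100, color="tab:green", label="cumulative accuracy")
    if trace.last_nonsignificant and trace.last_nonsignificant > 0:
        ax.axvline(trace.last_nonsignificant, color="red", label="last nonsignificant")
    ax.set_xlabel("trial")
    ax.set_ylabel("cumulative percent correct")
    ax.set_ylim(0, 100)
    ax.legend(loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    if n_rows == 2:
        ax2 = axes[1][0]
        ax2.fill_between(x, trace.ang_env_low, trace.ang_env_high, color="0.8")
        ax2.plot(x, trace.mean_angular_error, color="tab:blue")
        if trace.last_nonsignificant_angular and trace.last_nonsignificant_angular > 0:
            ax2.axvline(trace.last_nonsignificant_angular, color="red")
        ax2.set_xlabel("trial")
        ax2.set_ylabel("mean angular error (deg)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
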