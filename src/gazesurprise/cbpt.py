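"""Cluster-based permutation testing of binned time series.

Two-condition contrasts of per-trial binned pupil series are tested
with the max-cluster-mass permutation scheme: per-bin Welch t-values
are thresholded at the two-sided p < .05 critical value, contiguous
sign-homogeneous suprathreshold bins form clusters whose t-values are
summed, and the observed cluster masses are referred to the null
distribution of the largest absolute cluster mass over label
permutations (by default 10,000 shuffles of trial condition labels
within subject).  This controls the family-wise error rate over bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_PERM = 10_000
CLUSTER_ALPHA = 0.05   # cluster-forming threshold (two-sided)
MASS_ALPHA = 0.05      # significance level on the permutation p-value


def binwise_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin two-sample Welch t and degrees of freedom.

    Parameters
    ----------
    x1, x2 : ndarray, shape (n_trials, n_bins)
        Trials of the two conditions on a shared bin grid.

    Returns
    -------
    t : ndarray of t-values per bin (positive when group 1 > group 2).
    df : ndarray of Welch-Satterthwaite degrees of freedom per bin.
    """
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs at least 2 trials")
    m1, m2 = x1.mean(0), x2.mean(0)
    v1, v2 = x1.var(0, ddof=1), x2.var(0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                     + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    return t, df


@dataclass
class Cluster:
    """A contiguous run of suprathreshold, sign-homogeneous bins."""

    start_bin: int
    stop_bin: int              # inclusive
    t_mass: float              # sum of in-cluster t-values (signed)
    p_mass: float = np.nan
    span_ms: tuple[float, float] | None = None

    @property
    def significant(self) -> bool:
        return self.p_mass < MASS_ALPHA


def find_clusters(t: np.ndarray, df: np.ndarray,
                  alpha: float = CLUSTER_ALPHA) -> list[Cluster]:
    """Maximal runs of bins exceeding the two-sided critical t, one sign."""
    t = np.asarray(t, float)
    crit = stats.t.ppf(1.0 - alpha / 2.0, np.asarray(df, float))
    above = np.abs(t) > crit
    sign = np.sign(t)
    clusters: list[Cluster] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        clusters.append(Cluster(start_bin=i, stop_bin=j,
                                t_mass=float(t[i:j + 1].sum())))
        i = j + 1
    return clusters


def _max_cluster_mass(t: np.ndarray, crit: np.ndarray) -> float:
    """Largest |sum of t| over suprathreshold sign-homogeneous runs (0 if none)."""
    above = np.abs(t) > crit
    if not above.any():
        return 0.0
    sign = np.sign(t)
    # new cluster at every start of a run or sign flip inside one
    brk = np.ones(len(t), dtype=bool)
    brk[1:] = (~above[:-1]) | (sign[1:] != sign[:-1])
    gid = np.cumsum(brk) - 1
    masses = np.bincount(gid[above], weights=t[above])
    return float(np.max(np.abs(masses)))


def _welch_from_sums(s1, q1, n1, s_tot, q_tot, n_tot):
    n2 = n_tot - n1
    m1 = s1 / n1
    m2 = (s_tot - s1) / n2
    v1 = (q1 - n1 * m1 ** 2) / (n1 - 1)
    v2 = ((q_tot - q1) - n2 * m2 ** 2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                     + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    return t, df


def permutation_null(x: np.ndarray, labels: np.ndarray,
                     subjects: np.ndarray | None,
                     n_perm: int = DEFAULT_N_PERM,
                     rng: np.random.Generator | None = None,
                     alpha: float = CLUSTER_ALPHA,
                     within_subject: bool = True) -> np.ndarray:
    """Null distribution of the largest absolute cluster mass.

    Each permutation shuffles the trial condition labels (within
    subject by default, preserving each subject's condition counts) and
    records the largest cluster |t-mass| of the shuffled data, or 0
    when no cluster forms.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, float)
    labels = np.asarray(labels, bool)
    n = len(labels)
    x2 = x ** 2
    s_tot = x.sum(0)
    q_tot = x2.sum(0)

    if within_subject and subjects is not None:
        codes = pd.factorize(subjects)[0]
        base_order = np.lexsort((np.arange(n), codes))
    else:
        codes = None

    null = np.empty(n_perm)
    for k in range(n_perm):
        if codes is not None:
            order = np.lexsort((rng.random(n), codes))
            lab = np.empty(n, dtype=bool)
            lab[order] = labels[base_order]
        else:
            lab = labels[rng.permutation(n)]
        s1 = lab @ x
        q1 = lab @ x2
        t, df = _welch_from_sums(s1, q1, lab.sum(), s_tot, q_tot, n)
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        null[k] = _max_cluster_mass(t, crit)
    return null


@dataclass
class ClusterPermutationResult:
    """Fitted cluster permutation test: observed clusters and their p-values."""

    clusters: list[Cluster]
    t_values: np.ndarray
    df: np.ndarray
    null_distribution: np.ndarray
    n_perm: int
    bin_centers: np.ndarray | None = None
    contrast: tuple = ()

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast),
            "n_perm": self.n_perm,
            "clusters": [{
                "start_bin": c.start_bin,
                "stop_bin": c.stop_bin,
                "span_ms": list(c.span_ms) if c.span_ms else None,
                "t_mass": c.t_mass,
                "p_mass": c.p_mass,
                "significant": bool(c.significant),
            } for c in self.clusters],
        }

    def plot(self, ax=None):
        """Plot the bin-wise t-values with significant clusters shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = (self.bin_centers if self.bin_centers is not None
             else np.arange(len(self.t_values)))
        ax.plot(x, self.t_values, color="k", lw=1.2)
        ax.axhline(0.0, color="grey", lw=0.5)
        for c in self.significant_clusters:
            ax.axvspan(x[c.start_bin], x[c.stop_bin], alpha=0.2,
                       color="tab:orange")
        ax.set_xlabel("time (ms)" if self.bin_centers is not None else "bin")
        ax.set_ylabel("t value")
        if self.contrast:
            ax.set_title(f"{self.contrast[0]} vs {self.contrast[1]}")
        return ax

    def summary(self) -> str:
        lines = [f"Cluster-based permutation test "
                 f"({self.n_perm} permutations)"]
        if self.contrast:
            lines[0] += f", contrast {self.contrast[0]} vs {self.contrast[1]}"
        if not self.clusters:
            lines.append("  no suprathreshold clusters")
        for c in self.clusters:
            span = (f"{c.span_ms[0]:.0f}-{c.span_ms[1]:.0f} ms"
                    if c.span_ms else f"bins {c.start_bin}-{c.stop_bin}")
            star = " *" if c.significant else ""
            lines.append(f"  {span}: t_mass = {c.t_mass:.2f}, "
                         f"p_mass = {c.p_mass:.4f}{star}")
        return "\n".join(lines)


class ClusterPermutation:
    """Two-condition cluster permutation model over binned trials.

    Parameters
    ----------
    x : ndarray, shape (n_trials, n_bins)
        Binned series, one row per trial.
    labels : ndarray of bool
        True for trials of the first condition.
    subjects : ndarray, optional
        Subject id per trial; enables within-subject label shuffling.
    bin_centers : ndarray, optional
        Bin centres in ms, used to report cluster spans in time.
    """

    def __init__(self, x: np.ndarray, labels: np.ndarray,
                 subjects: np.ndarray | None = None,
                 bin_centers: np.ndarray | None = None,
                 contrast: tuple = ()):
        self.x = np.asarray(x, float)
        self.labels = np.asarray(labels, bool)
        self.subjects = None if subjects is None else np.asarray(subjects)
        self.bin_centers = (None if bin_centers is None
                            else np.asarray(bin_centers, float))
        self.contrast = contrast
        if self.labels.sum() < 2 or (~self.labels).sum() < 2:
            raise ValueError("each condition needs at least 2 trials")

    @classmethod
    def from_bins_frame(cls, bins: pd.DataFrame,
                        contrast: tuple[int, int]) -> "ClusterPermutation":
        """Build from a tidy bins table (subject, trial_id, condition,
        bin_center_ms, value_mm) for two condition levels."""
        sub = bins[bins["condition"].isin(contrast)]
        wide = sub.pivot_table(index=["subject", "trial_id", "condition"],
                               columns="bin_center_ms", values="value_mm",
                               sort=True)
        idx = wide.index.to_frame(index=False)
        return cls(wide.to_numpy(),
                   labels=(idx["condition"] == contrast[0]).to_numpy(),
                   subjects=idx["subject"].to_numpy(),
                   bin_centers=wide.columns.to_numpy(float),
                   contrast=contrast)

    def fit(self, n_perm: int = DEFAULT_N_PERM,
            seed: int | np.random.Generator | None = None,
            within_subject: bool = True) -> ClusterPermutationResult:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        t, df = binwise_t(self.x[self.labels], self.x[~self.labels])
        clusters = find_clusters(t, df)
        null = permutation_null(self.x, self.labels, self.subjects,
                                n_perm=n_perm, rng=rng,
                                within_subject=within_subject)
        for c in clusters:
            c.p_mass = float((1 + np.sum(null >= abs(c.t_mass)))
                             / (1 + n_perm))
            if self.bin_centers is not None:
                half = (np.median(np.diff(self.bin_centers)) / 2.0
                        if len(self.bin_centers) > 1 else 25.0)
                c.span_ms = (float(self.bin_centers[c.start_bin] - half),
                             float(self.bin_centers[c.stop_bin] + half))
        return ClusterPermutationResult(
            clusters=clusters, t_values=t, df=df, null_distribution=null,
            n_perm=n_perm, bin_centers=self.bin_centers,
            contrast=self.contrast)
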