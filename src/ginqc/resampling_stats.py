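"""Leave-one-unit-out cross-validation of HWEP, group tests, exact Spearman.

The HWEP size of a batch depends on which markers (primers) or which
fingerprint peaks went into the entropy. To expose unit-specific bias, the
pipeline recomputes the full entropy -> RSD -> n -> MQS chain once per
excluded unit — one primer per fold for band data, one common peak per fold
for fingerprints — and summarises each batch as mean ± SE over the folds.

Small-sample rank correlation between genetic and chemical HWEP sizes is
computed with an exact permutation p-value (full enumeration of rank
permutations up to n = 9), since asymptotic approximations are unreliable at
the handful-of-batches scale these studies run at.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import entropy_hwep, marker_io
from .entropy_hwep import HwepConfig

__all__ = [
    "LoocvResult",
    "CorrelationResult",
    "loocv_genetic",
    "loocv_chemical",
    "group_compare",
    "GroupCompareResult",
    "spearman_exact",
]

EXACT_PERMUTATION_MAX_N = 9  # n! enumeration stays cheap up to here


@dataclass
class LoocvResult:
    """Per-fold batch reports plus mean ± SE summaries.

    ``folds`` maps the excluded unit id to its batch report (the frame from
    :func:`ginqc.entropy_hwep.batch_hwep_report`); ``summary`` has one row per
    batch with mean and SE (sd / sqrt(fold_count)) of n and MQS over folds.
    """

    folds: dict[str, pd.DataFrame]
    flagged: dict[str, str] = field(default_factory=dict)

    @property
    def fold_count(self) -> int:
        return len(self.folds)

    @property
    def summary(self) -> pd.DataFrame:
        k = self.fold_count
        n_by_batch = pd.DataFrame({u: r["n"] for u, r in self.folds.items()})
        m_by_batch = pd.DataFrame({u: r["MQS_kg"] for u, r in self.folds.items()})
        return pd.DataFrame(
            {
                "mean_n": n_by_batch.mean(axis=1),
                "se_n": n_by_batch.std(axis=1, ddof=1) / math.sqrt(k),
                "mean_MQS_kg": m_by_batch.mean(axis=1),
                "se_MQS_kg": m_by_batch.std(axis=1, ddof=1) / math.sqrt(k),
                "fold_count": k,
            }
        )

    def n_values(self, batch_id: str) -> pd.Series:
        """The per-fold HWEP sizes of one batch (for group comparisons)."""
        return pd.Series({u: r.loc[batch_id, "n"] for u, r in self.folds.items()})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_count": self.fold_count,
            "flagged": self.flagged,
            "folds": {
                u: json.loads(r.to_json(orient="index")) for u, r in self.folds.items()
            },
            "summary": json.loads(self.summary.to_json(orient="index")),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def loocv_genetic(bm, cfg: HwepConfig = HwepConfig()) -> LoocvResult:
    """Leave-one-primer-out HWEP: one fold per primer of the panel.

    Each fold drops one primer's bands, recomputes m1, per-sample m2 and H,
    then batch RSD, n and MQS. A fold in which some sample amplifies no
    remaining band has undefined entropy; it is flagged and excluded from the
    summaries with a warning.
    """
    primers = bm.primer_ids
    if len(primers) < 2:
        raise ValueError("leave-one-primer-out needs at least 2 primers")
    folds: dict[str, pd.DataFrame] = {}
    flagged: dict[str, str] = {}
    for pid in primers:
        sub = marker_io.exclude_primer(bm, pid)
        if (sub.m2 == 0).any():
            empty = list(sub.m2.index[sub.m2 == 0])
            flagged[pid] = f"samples with no remaining bands: {empty}"
            warnings.warn(
                f"fold excluding {pid!r} flagged ({flagged[pid]}); dropped from summary",
                stacklevel=2,
            )
            continue
        ent = entropy_hwep.batch_entropies_genetic(sub, cfg)
        folds[pid] = entropy_hwep.batch_hwep_report(ent, cfg)
    return LoocvResult(folds, flagged)


def loocv_chemical(pt, batch_map, cfg: HwepConfig = HwepConfig()) -> LoocvResult:
    """Leave-one-peak-out HWEP: one fold per common peak of the table."""
    peaks = pt.peak_ids
    if len(peaks) < 2:
        raise ValueError("leave-one-peak-out needs at least 2 peaks")
    folds: dict[str, pd.DataFrame] = {}
    flagged: dict[str, str] = {}
    for peak in peaks:
        sub = pt.drop_peak(peak)
        zero = sub.areas.sum(axis=1) == 0
        if zero.any():
            flagged[peak] = f"samples left all-zero: {list(sub.areas.index[zero])}"
            warnings.warn(
                f"fold excluding {peak!r} flagged ({flagged[peak]}); dropped from summary",
                stacklevel=2,
            )
            continue
        ent = entropy_hwep.batch_entropies_chemical(sub, batch_map, cfg)
        folds[peak] = entropy_hwep.batch_hwep_report(ent, cfg)
    return LoocvResult(folds, flagged)


@dataclass(frozen=True)
class GroupCompareResult:
    design: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    pairwise: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def _all_identical(groups: dict) -> bool:
    pooled = np.concatenate([np.asarray(v, float) for v in groups.values()])
    return bool(np.all(pooled == pooled[0]))


def group_compare(groups: dict, design: str = "two_sample_welch") -> GroupCompareResult:
    """Standard group-difference tests used around HWEP comparisons.

    designs: ``two_sample_welch`` (unequal-variance t), ``paired_t``, and
    ``one_way_anova_lsd`` (one-way ANOVA plus Fisher's LSD pairwise t-tests on
    the pooled error term, with compact-letter display). When every value in
    every group is identical the comparison is degenerate and p = 1 is
    reported.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    if _all_identical(groups):
        return GroupCompareResult(design, 0.0, 0.0, 1.0)
    labels = list(groups)
    if design == "two_sample_welch":
        if len(labels) != 2:
            raise ValueError("two_sample_welch needs exactly 2 groups")
        res = stats.ttest_ind(groups[labels[0]], groups[labels[1]], equal_var=False)
        return GroupCompareResult(design, float(res.statistic), float(res.df), float(res.pvalue))
    if design == "paired_t":
        if len(labels) != 2:
            raise ValueError("paired_t needs exactly 2 groups")
        a, b = groups[labels[0]], groups[labels[1]]
        if a.size != b.size:
            raise ValueError("paired_t needs equal-length groups")
        res = stats.ttest_rel(a, b)
        return GroupCompareResult(design, float(res.statistic), float(a.size - 1), float(res.pvalue))
    if design != "one_way_anova_lsd":
        raise ValueError(f"unknown design {design!r}")
    f_res = stats.f_oneway(*[groups[k] for k in labels])
    n_total = sum(v.size for v in groups.values())
    df_within = n_total - len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_within
    rows = []
    for ka, kb in itertools.combinations(labels, 2):
        a, b = groups[ka], groups[kb]
        se = math.sqrt(mse * (1 / a.size + 1 / b.size))
        t = (a.mean() - b.mean()) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df_within) if se > 0 else 1.0
        rows.append({"group_a": ka, "group_b": kb, "t": t, "p": p})
    pairwise = pd.DataFrame(rows)
    letters = _lsd_letters(labels, {k: groups[k].mean() for k in labels}, pairwise)
    return GroupCompareResult(
        design,
        float(f_res.statistic),
        (float(len(labels) - 1), float(df_within)),
        float(f_res.pvalue),
        pairwise=pairwise,
        letters=letters,
    )


def _lsd_letters(labels, means, pairwise, alpha: float = 0.05) -> dict[str, str]:
    """Compact-letter display: groups sharing a letter are not significantly
    different pairwise at ``alpha`` (presentation only)."""
    sig = {
        frozenset((r.group_a, r.group_b)): r.p < alpha for r in pairwise.itertuples()
    }
    ordered = sorted(labels, key=lambda k: -means[k])
    letter_sets: list[list[str]] = []  # groups carrying each letter
    for g in ordered:
        placed = False
        for members in letter_sets:
            if all(not sig[frozenset((g, m))] for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    out = {g: "" for g in labels}
    for i, members in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in members:
            out[g] += ch
    return out


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int
    method: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"rho": self.rho, "p_value": self.p_value,
                 "n_pairs": self.n_pairs, "method": self.method},
                indent=2,
            )
            + "\n"
        )


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    n = rx.size
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_exact(x, y) -> CorrelationResult:
    """Spearman rank correlation with an exact two-sided permutation p.

    rho = 1 − 6 Σd² / (n(n²−1)) on average ranks. For n ≤ 9 the p-value
    enumerates all n! permutations of one rank vector and counts
    |rho_perm| ≥ |rho_obs| (method ``exact_permutation``); larger n falls back
    to the asymptotic t approximation (method ``asymptotic``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        target = abs(rho) - 1e-12
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            if abs(_rho_from_ranks(rx, np.asarray(perm))) >= target:
                count += 1
        return CorrelationResult(rho, count / total, n, "exact_permutation")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
    p = float(min(1.0, 2 * stats.t.sf(abs(t), n - 2)))
    return CorrelationResult(rho, p, n, "asymptotic")
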