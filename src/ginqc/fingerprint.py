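"""Chromatographic fingerprint handling: common peaks, relative metrics, similarity.

A fingerprint study reduces each sample's chromatogram to a list of (retention
time, area) peaks, aligns the peaks shared by every sample ("common peaks"),
and compares samples by the cosine (congruence) coefficient of their area
vectors — the default metric of pharmacopoeia fingerprint-similarity software.
Relative retention time (RRT) and relative peak area (RPA), ratios to a
designated reference peak, are the method-validation metrics and the basis of
alignment: RRT is insensitive to uniform retention shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import within_batch_similarity

__all__ = [
    "PeakList",
    "PeakTable",
    "relative_metrics",
    "match_common_peaks",
    "fingerprint_similarity",
    "within_batch_fingerprint_similarity",
]


@dataclass
class PeakList:
    """One sample's detected peaks: retention times (minutes) and areas."""

    sample_id: str
    retention_times: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.retention_times, dtype=float)
        ar = np.asarray(self.areas, dtype=float)
        if rt.shape != ar.shape or rt.ndim != 1 or rt.size == 0:
            raise ValueError("retention_times and areas must be equal-length 1-D")
        if (np.diff(rt) <= 0).any():
            raise ValueError(f"retention times must be strictly increasing ({self.sample_id})")
        if (ar < 0).any():
            raise ValueError(f"negative peak area ({self.sample_id})")
        self.retention_times = rt
        self.areas = ar

    def __len__(self) -> int:
        return self.retention_times.size

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None) -> "PeakList":
        """Read (sample_id, rt_min, area) rows; sorts by retention time."""
        df = pd.read_csv(path, sep=None, engine="python")
        sid = sample_id or str(df.iloc[0, 0])
        df = df.sort_values(df.columns[1])
        return cls(sid, df.iloc[:, 1].to_numpy(float), df.iloc[:, 2].to_numpy(float))


@dataclass
class PeakTable:
    """Aligned common-peak areas: samples x peaks, no missing cells.

    ``peak_labels`` optionally names identified peaks (e.g. the ginsenosides
    Rg1, Re, Rb1) so a reduced characteristic-peak panel can be selected.
    """

    areas: pd.DataFrame
    peak_labels: dict[str, str] = field(default_factory=dict)
    reference_peak_id: str | None = None
    retention_times: dict[str, float] = field(default_factory=dict)  # template RT per peak

    def __post_init__(self) -> None:
        if self.areas.isna().any().any():
            raise ValueError("peak table has missing cells")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        unknown = set(self.peak_labels) - set(self.areas.columns)
        if unknown:
            raise ValueError(f"labels for unknown peaks: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    def select_labels(self, labels) -> "PeakTable":
        """Restrict to the peaks carrying any of the given labels (order kept)."""
        wanted = set(labels)
        keep = [p for p in self.areas.columns if self.peak_labels.get(p) in wanted]
        if not keep:
            raise ValueError(f"no peak carries a label in {sorted(wanted)}")
        return PeakTable(
            self.areas[keep].copy(),
            {p: l for p, l in self.peak_labels.items() if p in keep},
            self.reference_peak_id if self.reference_peak_id in keep else None,
        )

    def drop_peak(self, peak_id: str) -> "PeakTable":
        if peak_id not in self.areas.columns:
            raise KeyError(peak_id)
        keep = [p for p in self.areas.columns if p != peak_id]
        return PeakTable(
            self.areas[keep].copy(),
            {p: l for p, l in self.peak_labels.items() if p != peak_id},
            self.reference_peak_id if self.reference_peak_id != peak_id else None,
        )

    def to_csv(self, path) -> None:
        self.areas.to_csv(path, index_label="sample_id")


def relative_metrics(pl: PeakList, reference_index: int) -> pd.DataFrame:
    """RRT and RPA of every peak against the reference peak.

    RRT_i = rt_i / rt_ref, RPA_i = area_i / area_ref; both are 1 at the
    reference and invariant to uniform scaling of all times / all areas.
    """
    if not 0 <= reference_index < len(pl):
        raise IndexError(f"reference peak index {reference_index} out of range")
    ref_rt = pl.retention_times[reference_index]
    ref_area = pl.areas[reference_index]
    if ref_area == 0:
        raise ValueError("reference peak has zero area")
    return pd.DataFrame(
        {
            "RRT": pl.retention_times / ref_rt,
            "RPA": pl.areas / ref_area,
        },
        index=pd.RangeIndex(len(pl), name="peak"),
    )


def _rrt(pl: PeakList) -> np.ndarray:
    """RRT against the sample's own largest-area peak (self-contained reference)."""
    ref = int(np.argmax(pl.areas))
    return pl.retention_times / pl.retention_times[ref]


def match_common_peaks(
    lists: list[PeakList], rrt_tolerance: float = 0.02, on: str = "rrt"
) -> PeakTable:
    """Align peaks across samples and keep those matched in every sample.

    The first sample's peaks are the templates. For each other sample, every
    template greedily takes the nearest unclaimed peak (smallest coordinate
    gap first) within ``rrt_tolerance``. A template matched in all samples is
    a common peak; the table holds its area per sample, columns ordered by
    template retention. ``on="rrt"`` (default) matches on retention times
    normalised to each sample's largest-area peak, which cancels uniform
    retention shifts; ``on="rt"`` matches raw retention times.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 samples to define common peaks")
    if on not in ("rrt", "rt"):
        raise ValueError("on must be 'rrt' or 'rt'")
    coords = [(_rrt(pl) if on == "rrt" else pl.retention_times) for pl in lists]
    template = lists[0]
    n_templ = len(template)
    # matched[i][s] = index of sample s's peak matched to template i
    matched: list[dict[int, int]] = [{s: i for s in (0,)} for i in range(n_templ)]
    per_sample_counts = [n_templ]
    for s in range(1, len(lists)):
        gaps = np.abs(coords[0][:, None] - coords[s][None, :])
        order = np.dstack(np.unravel_index(np.argsort(gaps, axis=None), gaps.shape))[0]
        used_t: set[int] = set()
        used_p: set[int] = set()
        count = 0
        for ti, pi in order:
            if gaps[ti, pi] > rrt_tolerance:
                break
            if ti in used_t or pi in used_p:
                continue
            used_t.add(int(ti))
            used_p.add(int(pi))
            matched[int(ti)][s] = int(pi)
            count += 1
        per_sample_counts.append(count)
    common = [i for i in range(n_templ) if len(matched[i]) == len(lists)]
    if not common:
        raise ValueError(
            "no common peaks across samples; per-sample match counts vs "
            f"template: {per_sample_counts}"
        )
    common.sort(key=lambda i: template.retention_times[i])
    peak_ids = [f"P{k + 1}" for k in range(len(common))]
    data = {
        pl.sample_id: [pl.areas[matched[i][s]] for i in common]
        for s, pl in enumerate(lists)
    }
    areas = pd.DataFrame(data, index=peak_ids).T
    rts = {pid: float(template.retention_times[i]) for pid, i in zip(peak_ids, common)}
    return PeakTable(areas, retention_times=rts)


def fingerprint_similarity(
    pt: PeakTable, reference: str = "mean"
) -> tuple[pd.Series, pd.DataFrame]:
    """Cosine (congruence) similarity of area vectors.

    Returns ``(per_sample, pairwise)``: each sample against the reference
    chromatogram (the cohort's arithmetic-mean area vector by default, or a
    named sample), and the full pairwise matrix for heatmaps. Cosine is scale
    invariant, so dilution differences between injections cancel.
    """
    X = pt.areas.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 peaks for a meaningful similarity")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [s for s, nz in zip(pt.sample_ids, norms == 0) if nz]
        raise ValueError(f"all-zero area vector(s): {bad}; similarity undefined")
    if reference == "mean":
        ref = X.mean(axis=0)
    else:
        if reference not in pt.areas.index:
            raise KeyError(f"reference sample {reference!r} not in table")
        ref = pt.areas.loc[reference].to_numpy(dtype=float)
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference chromatogram is all-zero")
    per_sample = pd.Series(X @ ref / (norms * ref_norm), index=pt.areas.index, name="similarity")
    unit = X / norms[:, None]
    pairwise = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(pairwise, 1.0)
    return per_sample, pd.DataFrame(pairwise, index=pt.areas.index, columns=pt.areas.index)


def within_batch_fingerprint_similarity(
    pairwise: pd.DataFrame, batch_map: dict | pd.Series
) -> pd.DataFrame:
    """Per-batch mean ± sd of pairwise fingerprint similarity (see similarity module)."""
    return within_batch_similarity(pairwise, batch_map)
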