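"""Synthetic band matrices and peak tables, plus the reference study tables.

The generators emulate the statistical structure the pipeline assumes, so
every stage is testable without external data:

* Band matrices — each batch descends from a founder profile (each band
  present with ``founder_presence_prob``); individual samples flip each band
  independently with ``flip_prob``. The flip rate is the dial for
  within-batch genetic heterogeneity: expected band-profile disagreement,
  entropy spread, and hence HWEP size all grow with it.
* Peak tables — each batch has a mean chromatogram; sample areas are the mean
  times a log-normal multiplicative factor with unit mean and the stated CV,
  which guarantees positivity and maps the CV directly onto the RSD scale the
  pipeline measures.

:func:`load_reference_tables` ships the digitized reference ginseng study
inputs (an 8-primer / 92-band ISSR panel over 21 samples in 7 batches, and
per-batch fingerprint entropies for a 6-common-peak and a 3-ginsenoside
panel) so the full entropy -> HWEP -> MQS chain can be exercised on real
published summary numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fingerprint import PeakList, PeakTable
from .marker_io import BandMatrix

__all__ = [
    "BandDesign",
    "PeakDesign",
    "generate_band_matrix",
    "generate_peak_table",
    "ReferenceTables",
    "load_reference_tables",
]


@dataclass(frozen=True)
class BandDesign:
    """Design of a synthetic multi-batch band matrix.

    ``primers`` maps primer_id -> band count; ``batches`` is a list of
    ``(batch_id, n_samples, founder_presence_prob, flip_prob)``.
    """

    primers: dict[str, int]
    batches: list[tuple[str, int, float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.primers or any(c < 1 for c in self.primers.values()):
            raise ValueError("every primer needs at least 1 band")
        for batch_id, n, fp, flip in self.batches:
            if n < 2:
                raise ValueError(f"batch {batch_id!r} needs >= 2 samples")
            if not (0 <= fp <= 1 and 0 <= flip <= 1):
                raise ValueError(f"batch {batch_id!r}: probabilities must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BandDesign":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            primers=dict(cfg["primers"]),
            batches=[tuple(b) for b in cfg["batches"]],
            seed=int(cfg.get("seed", 0)),
        )


def generate_band_matrix(design: BandDesign, max_founder_retries: int = 100) -> BandMatrix:
    """Draw a batch-structured 0/1 band matrix (deterministic per seed).

    Per batch: one founder profile, then per-sample independent band flips.
    An all-zero founder (possible at tiny presence probability) is redrawn up
    to ``max_founder_retries`` times, then rejected.
    """
    rng = np.random.default_rng(design.seed)
    band_ids = [
        f"{pid}:{k + 1}" for pid, count in design.primers.items() for k in range(count)
    ]
    n_bands = len(band_ids)
    rows, sample_ids, batch_of = [], [], {}
    for batch_id, n_samples, founder_p, flip_p in design.batches:
        founder = None
        for _ in range(max_founder_retries):
            cand = rng.random(n_bands) < founder_p
            if cand.any():
                founder = cand
                break
        if founder is None:
            raise ValueError(
                f"batch {batch_id!r}: founder all-zero after {max_founder_retries} draws "
                f"(founder_presence_prob={founder_p})"
            )
        for i in range(n_samples):
            flips = rng.random(n_bands) < flip_p
            rows.append(np.where(flips, ~founder, founder).astype(np.int8))
            sid = f"{batch_id}-{i + 1}"
            sample_ids.append(sid)
            batch_of[sid] = batch_id
    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=band_ids)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero bands are expected under random designs
        return BandMatrix(values, pd.Series(batch_of))


@dataclass(frozen=True)
class PeakDesign:
    """Design of a synthetic common-peak area table.

    ``batches`` is a list of ``(batch_id, n_samples, mean_areas, cv)`` where
    ``mean_areas`` has one positive entry per peak and ``cv`` is the
    multiplicative coefficient of variation of the log-normal noise.
    """

    n_peaks: int
    batches: list[tuple[str, int, tuple, float]]
    seed: int = 0
    retention_times: tuple = ()

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("need at least one peak")
        for batch_id, n, means, cv in self.batches:
            means = np.asarray(means, dtype=float)
            if means.size != self.n_peaks or (means <= 0).any():
                raise ValueError(f"batch {batch_id!r}: mean_areas must be {self.n_peaks} positive values")
            if n < 2 or cv < 0:
                raise ValueError(f"batch {batch_id!r}: need n >= 2 and cv >= 0")
        if self.retention_times and len(self.retention_times) != self.n_peaks:
            raise ValueError("retention_times must match n_peaks")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean log-normal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_peak_table(
    design: PeakDesign, rt_jitter_sd: float = 0.0
) -> tuple[PeakTable, pd.Series, list[PeakList]]:
    """Draw a peak table: ``area = mean_area * LogNormal(unit mean, CV)``.

    Returns ``(table, batch_map, peak_lists)``; the per-sample
    :class:`PeakList` objects (built when the design carries retention times)
    add Gaussian retention jitter of sd ``rt_jitter_sd`` minutes for
    peak-matching tests. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    peak_ids = [f"P{k + 1}" for k in range(design.n_peaks)]
    rows, sample_ids, batch_of = [], [], {}
    for batch_id, n_samples, means, cv in design.batches:
        means = np.asarray(means, dtype=float)
        for i in range(n_samples):
            rows.append(means * _lognormal_factors(rng, cv, design.n_peaks))
            sid = f"{batch_id}-{i + 1}"
            sample_ids.append(sid)
            batch_of[sid] = batch_id
    areas = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=peak_ids)
    table = PeakTable(areas)
    lists: list[PeakList] = []
    if design.retention_times:
        rts = np.asarray(design.retention_times, dtype=float)
        for sid in sample_ids:
            jitter = rng.normal(0.0, rt_jitter_sd, design.n_peaks) if rt_jitter_sd else 0.0
            rt = np.sort(rts + jitter)
            lists.append(PeakList(sid, rt, table.areas.loc[sid].to_numpy()))
    return table, pd.Series(batch_of), lists


# ---------------------------------------------------------------------------
# Reference study tables (digitized published inputs; not synthetic)
# ---------------------------------------------------------------------------

# Per-primer band counts of the 8-primer ISSR panel: TNB total bands,
# NPB polymorphic bands over the 21 samples.
_PRIMER_ROWS = [
    ("UBC807", "AGAGAGAGAGAGAGAGT", 14, 12),
    ("UBC808", "AGAGAGAGAGAGAGAGC", 12, 12),
    ("UBC809", "AGAGAGAGAGAGAGAGG", 5, 3),
    ("UBC823", "TCTCTCTCTCTCTCTCC", 13, 12),
    ("UBC834", "AGAGAGAGAGAGAGAGYT", 13, 10),
    ("UBC840", "GAGAGAGAGAGAGAGAYT", 10, 9),
    ("UBC842", "GAGAGAGAGAGAGAGAYG", 11, 8),
    ("UBC873", "GACAGACAGACAGACA", 14, 14),
]

# Observed band counts (m2) per sample on the 92-band panel; three replicate
# decoction pieces / plants per batch. PG: decoction-piece batches, GG: garden
# ginseng, FG: ginseng grown under forest.
_BAND_COUNT_ROWS = [
    ("PG01-1", "PG01", 70), ("PG01-2", "PG01", 72), ("PG01-3", "PG01", 70),
    ("PG02-1", "PG02", 33), ("PG02-2", "PG02", 37), ("PG02-3", "PG02", 34),
    ("PG03-1", "PG03", 47), ("PG03-2", "PG03", 41), ("PG03-3", "PG03", 47),
    ("PG04-1", "PG04", 37), ("PG04-2", "PG04", 40), ("PG04-3", "PG04", 38),
    ("PG05-1", "PG05", 36), ("PG05-2", "PG05", 42), ("PG05-3", "PG05", 40),
    ("GG1", "GG", 81), ("GG2", "GG", 82), ("GG3", "GG", 81),
    ("FG1", "FG", 50), ("FG2", "FG", 47), ("FG3", "FG", 53),
]

# Published per-sample fingerprint entropies (response units x nats, three
# significant figures) for the 6-common-peak and the 3-ginsenoside
# (Rg1/Re/Rb1) characteristic-peak panels.
_FP_ENTROPY_6PEAK = {
    "PG01": (1.08e5, 9.26e4, 9.09e4),
    "PG02": (2.44e5, 2.05e5, 1.36e5),
    "PG03": (7.52e4, 4.51e4, 3.92e4),
    "PG04": (1.73e5, 1.57e5, 1.57e5),
    "PG05": (1.73e5, 1.39e5, 1.23e5),
    "GG": (2.54e4, 2.48e4, 2.15e4),
    "FG": (3.64e4, 3.52e4, 8.09e4),
}
_FP_ENTROPY_3GINSENOSIDE = {
    "PG01": (1.01e5, 8.81e4, 8.66e4),
    "PG02": (1.61e5, 1.88e5, 1.23e5),
    "PG03": (7.39e4, 3.59e4, 3.92e4),
    "PG04": (1.57e5, 1.42e5, 1.43e5),
    "PG05": (1.60e5, 1.31e5, 1.20e5),
    "GG": (1.84e4, 2.09e4, 1.88e4),
    "FG": (3.33e4, 3.44e4, 7.68e4),
}


@dataclass(frozen=True)
class ReferenceTables:
    """Machine-readable inputs of the reference ginseng study.

    ``primer_stats``: per-primer TNB/NPB; ``band_counts``: per-sample m2 with
    batch; ``fingerprint_entropy``: per-sample Sp for both characteristic-peak
    panels; ``panel_total_bands``: the full-panel m1 (92).
    """

    primer_stats: pd.DataFrame
    band_counts: pd.DataFrame
    fingerprint_entropy: pd.DataFrame
    panel_total_bands: int = 92
    source: str = "published multi-batch ginseng ISSR + UPLC fingerprint study"

    def entropy_groups(self, panel: str) -> dict[str, np.ndarray]:
        """batch_id -> fingerprint entropies for panel '6peak' or '3ginsenoside'."""
        col = {"6peak": "six_peak", "3ginsenoside": "three_ginsenoside"}[panel]
        return {
            b: g[col].to_numpy()
            for b, g in self.fingerprint_entropy.groupby("batch_id", sort=False)
        }


def load_reference_tables() -> ReferenceTables:
    """The reference study's primer panel counts, band counts and entropies."""
    primer = pd.DataFrame(
        _PRIMER_ROWS, columns=["primer_id", "sequence", "TNB", "NPB"]
    ).set_index("primer_id")
    primer["PPB"] = 100.0 * primer["NPB"] / primer["TNB"]
    bands = pd.DataFrame(
        _BAND_COUNT_ROWS, columns=["sample_id", "batch_id", "m2"]
    ).set_index("sample_id")
    fp_rows = []
    for batch in _FP_ENTROPY_6PEAK:
        for rep, (s6, s3) in enumerate(
            zip(_FP_ENTROPY_6PEAK[batch], _FP_ENTROPY_3GINSENOSIDE[batch]), start=1
        ):
            fp_rows.append(
                {"batch_id": batch, "replicate": rep, "six_peak": s6, "three_ginsenoside": s3}
            )
    return ReferenceTables(primer, bands, pd.DataFrame(fp_rows))
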