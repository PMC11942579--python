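"""Reading, validation and per-primer summaries of dominant-marker band matrices.

Dominant markers (ISSR, RAPD and the like) are scored from gels as band
present/absent, so a study's raw genetic data is a binary matrix of samples by
bands, each band amplified by one primer. This module owns that container
(:class:`BandMatrix`), its delimited-text dialect, the per-primer polymorphism
summary (TNB / NPB / PPB), and the column-subsetting used by
leave-one-primer-out resampling.

Band identity convention: ``band_id = "<primer_id>:<ordinal>"`` — the owning
primer is recoverable from the id, which makes primer exclusion a pure column
filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PrimerPanel",
    "BandMatrix",
    "PrimerStats",
    "read_band_matrix",
    "write_band_matrix",
    "primer_band_stats",
    "exclude_primer",
]

logger = logging.getLogger(__name__)


class BandMatrixError(ValueError):
    """Schema or parse failure in band-matrix input."""


@dataclass(frozen=True)
class PrimerPanel:
    """The primer set used for amplification.

    Parameters
    ----------
    primers : dict
        Mapping ``primer_id -> sequence`` (IUPAC DNA; empty string when the
        sequence is not recorded).
    """

    primers: dict[str, str]

    def __post_init__(self) -> None:
        if not self.primers:
            raise BandMatrixError("primer panel is empty")
        for pid in self.primers:
            if not pid:
                raise BandMatrixError("primer ids must be non-empty")

    @property
    def primer_ids(self) -> list[str]:
        return list(self.primers)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrimerPanel":
        """Read a two-column (primer_id, sequence) TSV/CSV panel."""
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        ids = df.iloc[:, 0].astype(str)
        if ids.duplicated().any():
            raise BandMatrixError(f"duplicate primer ids in {path}")
        seqs = df.iloc[:, 1].fillna("") if df.shape[1] > 1 else [""] * len(ids)
        return cls(dict(zip(ids, seqs)))


def _primer_of(band_id: str) -> str:
    """Owning primer from a ``primer:ordinal`` band id."""
    primer, sep, _ = str(band_id).partition(":")
    if not sep or not primer:
        raise BandMatrixError(
            f"band id {band_id!r} does not follow the '<primer>:<label>' convention"
        )
    return primer


@dataclass
class BandMatrix:
    """Binary presence/absence of amplified bands per sample.

    Attributes
    ----------
    values : pandas.DataFrame
        0/1 integer matrix, index = sample ids, columns = band ids
        (``"<primer>:<label>"``).
    batch_map : pandas.Series
        ``sample_id -> batch_id`` for every sample in ``values``.
    panel : PrimerPanel, optional
        When given, every band's primer must be a member.
    """

    values: pd.DataFrame
    batch_map: pd.Series
    panel: PrimerPanel | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise BandMatrixError("duplicate sample ids")
        if v.columns.duplicated().any():
            raise BandMatrixError("duplicate band ids")
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise BandMatrixError(
                f"non-binary entry at sample {v.index[bad[0]]!r}, band {v.columns[bad[1]]!r}"
            )
        self.values = v.astype(np.int8)
        primers = {_primer_of(b) for b in v.columns}
        if self.panel is not None:
            unknown = primers - set(self.panel.primer_ids)
            if unknown:
                raise BandMatrixError(f"bands reference primers not in panel: {sorted(unknown)}")
        bm = pd.Series(self.batch_map)
        missing = [s for s in v.index if s not in bm.index]
        if missing:
            raise BandMatrixError(f"samples missing from batch map: {missing}")
        self.batch_map = bm.reindex(v.index)
        never_seen = [b for b in v.columns if v[b].sum() == 0]
        if never_seen:
            # legal but suspicious: a band that never appears would not have
            # been scored on a gel
            warnings.warn(
                f"{len(never_seen)} band(s) absent in every sample: {never_seen[:5]}",
                stacklevel=2,
            )

    # -- bookkeeping -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def primer_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.values.columns:
            seen.setdefault(_primer_of(b), None)
        return list(seen)

    @property
    def band_primers(self) -> pd.Series:
        """band_id -> primer_id for every column."""
        return pd.Series({b: _primer_of(b) for b in self.values.columns})

    @property
    def m1(self) -> int:
        """Total band count of the panel as scored (the entropy denominator)."""
        return self.values.shape[1]

    @property
    def m2(self) -> pd.Series:
        """Per-sample count of observed (1) bands."""
        return self.values.sum(axis=1).astype(int)

    def bands_of(self, primer_id: str) -> list[str]:
        return [b for b in self.values.columns if _primer_of(b) == primer_id]


def read_band_matrix(
    path: str | Path,
    batch_map: str | Path | dict | pd.Series,
    panel: PrimerPanel | None = None,
    missing: str = "fail",
) -> BandMatrix:
    """Read a delimited band matrix (header = band ids, first column = sample id).

    ``missing`` controls NA policy: ``"fail"`` (default, strict — gel scoring
    yields no missing calls) or ``"as-absent"`` (NA recoded to 0).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    df.index.name = None
    df.columns.name = None
    if df.isna().any().any():
        if missing == "as-absent":
            df = df.fillna("0")
        else:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise BandMatrixError(
                f"missing call at sample {df.index[r]!r}, band {df.columns[c]!r} "
                "(pass missing='as-absent' to recode)"
            )
    try:
        mat = df.astype(float)
    except ValueError as exc:
        raise BandMatrixError(f"non-numeric band call in {path}: {exc}") from exc
    if not np.isin(mat.to_numpy(), (0.0, 1.0)).all():
        r, c = np.argwhere(~np.isin(mat.to_numpy(), (0.0, 1.0)))[0]
        raise BandMatrixError(
            f"non-binary entry {df.iat[r, c]!r} at sample {df.index[r]!r}, "
            f"band {df.columns[c]!r}"
        )
    if isinstance(batch_map, (str, Path)):
        bmap_df = pd.read_csv(batch_map, sep=None, engine="python", dtype=str)
        bmap = pd.Series(bmap_df.iloc[:, 1].values, index=bmap_df.iloc[:, 0].values)
    else:
        bmap = pd.Series(batch_map)
    bm = BandMatrix(mat.astype(np.int8), bmap, panel=panel)
    counts = bm.band_primers.value_counts()
    logger.info(
        "read band matrix: %d samples x %d bands, %d primers (%s)",
        len(bm.sample_ids), bm.m1, len(counts), counts.to_dict(),
    )
    return bm


def write_band_matrix(bm: BandMatrix, path: str | Path, batch_map_path: str | Path | None = None) -> None:
    """Write the 0/1 matrix (and optionally the batch map) as delimited text."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    bm.values.to_csv(path, sep=sep, index_label="sample_id")
    if batch_map_path is not None:
        bm.batch_map.rename("batch_id").to_csv(
            batch_map_path, sep=sep, index_label="sample_id"
        )


@dataclass(frozen=True)
class PrimerStats:
    """Per-primer band polymorphism summary.

    ``per_primer`` has one row per primer with columns ``TNB`` (total bands),
    ``NPB`` (polymorphic bands: neither present in all samples nor absent in
    all), and ``PPB`` (percent polymorphic). Panel totals pool counts before
    taking the rate: ``pooled_ppb = 100 * sum(NPB) / sum(TNB)``.
    """

    per_primer: pd.DataFrame
    total_tnb: int = field(default=0)
    total_npb: int = field(default=0)

    @property
    def pooled_ppb(self) -> float:
        return 100.0 * self.total_npb / self.total_tnb


def primer_band_stats(bm: BandMatrix) -> PrimerStats:
    """TNB/NPB/PPB per primer and pooled over the panel.

    A band is polymorphic when its column is neither all ones nor all zeros
    across the samples; with a single sample that is undefined.
    """
    if len(bm.sample_ids) < 2:
        raise BandMatrixError("polymorphism is undefined for a single-sample matrix")
    n = len(bm.sample_ids)
    colsum = bm.values.sum(axis=0)
    poly = (colsum > 0) & (colsum < n)
    rows = []
    for pid in bm.primer_ids:
        bands = bm.bands_of(pid)
        tnb = len(bands)
        npb = int(poly[bands].sum())
        rows.append((pid, tnb, npb, 100.0 * npb / tnb))
    per = pd.DataFrame(rows, columns=["primer_id", "TNB", "NPB", "PPB"]).set_index("primer_id")
    return PrimerStats(per, int(per["TNB"].sum()), int(per["NPB"].sum()))


def exclude_primer(bm: BandMatrix, primer_id: str) -> BandMatrix:
    """Drop every band amplified by ``primer_id`` (a leave-one-primer-out fold)."""
    if primer_id not in bm.primer_ids:
        raise KeyError(f"primer {primer_id!r} owns no band in this matrix")
    keep = [b for b in bm.values.columns if _primer_of(b) != primer_id]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero columns already flagged on first build
        return BandMatrix(bm.values[keep].copy(), bm.batch_map.copy(), panel=bm.panel)
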