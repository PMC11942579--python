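"""Information entropy of band profiles and fingerprints, HWEP size, and MQS.

The heterogeneity index at the core of the pipeline converts each sample's
profile into an information entropy, measures the within-batch fluctuation of
that entropy as a relative standard deviation (RSD), and maps the RSD onto the
size of a Hardy-Weinberg equilibrium population (HWEP) — the number of 1-gram
medicinal units over which the fluctuation is balanced at the chosen
confidence. The minimum quantity for one sampling (MQS) is that count times
the unit mass.

Formulas
--------
Band entropy of a sample amplifying ``m2`` of the panel's ``m1`` bands::

    H = -C * ln(m2 / m1)          (C = 1/ln 2 by default, so H is in bits)

Fingerprint entropy of a sample with common-peak areas a_i (f_i = a_i / sum a)::

    Sp = -sum_i a_i * ln(f_i)     (response units x nats; Sp >= 0)

HWEP size from the batch RSD of those entropies (RSD as a fraction)::

    table_consistent (default):  n = 100 * (t_{alpha,n-1} + u_beta)^2 * RSD^2
                                   = 100 * 10.8^2 * RSD^2
    eq5_literal:                 n = K * RSD^2          (K = 25.6)

The quantile sum 10.8 corresponds to type-I and type-II error levels of 0.05
each. The two modes differ by the constant factor ``100 * 10.8^2 / K``
(~455.6 for the defaults); only ``table_consistent`` reproduces published
batch tables, so ``eq5_literal`` is retained for comparison and logs a
warning when used.

MQS = n x unit_mass, reported in kilograms (the default unit weighs 1.000 g).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HwepConfig",
    "band_entropy",
    "batch_entropies_genetic",
    "batch_entropies_chemical",
    "fingerprint_entropy",
    "batch_rsd",
    "hwep_size",
    "mqs",
    "batch_hwep_report",
    "write_report",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

FORMULA_MODES = ("table_consistent", "eq5_literal")


@dataclass(frozen=True)
class HwepConfig:
    """Constants of the entropy -> HWEP -> MQS chain.

    Attributes
    ----------
    C : float
        Entropy conversion constant; 1/ln 2 gives entropy in bits.
    t_plus_u : float
        The quantile sum t_{alpha,n-1} + u_beta; 10.8 at alpha = beta = 0.05.
    formula_mode : str
        ``"table_consistent"`` (n = 100 * t_plus_u^2 * RSD^2, the default for
        both genetic and chemical data) or ``"eq5_literal"`` (n = K * RSD^2).
    K : float
        Formulation control coefficient, used only in ``eq5_literal`` mode.
    unit_mass_g : float
        Mass of one equilibrium unit in grams.
    """

    C: float = 1.0 / LN2
    t_plus_u: float = 10.8
    formula_mode: str = "table_consistent"
    K: float = 25.6
    unit_mass_g: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.t_plus_u <= 0 or self.K <= 0 or self.unit_mass_g <= 0:
            raise ValueError("HwepConfig constants must be positive")
        if self.formula_mode not in FORMULA_MODES:
            raise ValueError(f"formula_mode must be one of {FORMULA_MODES}")


class EntropyDomainError(ValueError):
    """Entropy requested outside its domain (empty profile, m2 > m1, ...)."""


def band_entropy(m2: int, m1: int, C: float = 1.0 / LN2) -> float:
    """Information entropy of a band profile: ``-C * ln(m2/m1)``.

    Zero at the full panel (m2 = m1); grows as fewer bands amplify. A sample
    amplifying nothing carries infinite entropy and is rejected.
    """
    if m2 > m1:
        raise EntropyDomainError(f"m2 ({m2}) exceeds panel total m1 ({m1})")
    if m2 <= 0:
        raise EntropyDomainError("m2 = 0: sample amplified no bands (infinite entropy)")
    if m1 <= 0:
        raise EntropyDomainError("m1 must be positive")
    return -C * math.log(m2 / m1)


def batch_entropies_genetic(bm, cfg: HwepConfig = HwepConfig()) -> pd.DataFrame:
    """Per-sample band entropies of a BandMatrix, one row per sample.

    Columns: ``batch_id``, ``m2``, ``m1``, ``entropy``; m1 is the band total
    of the (possibly primer-excluded) panel.
    """
    m1 = bm.m1
    m2 = bm.m2
    rows = []
    for sample in bm.sample_ids:
        rows.append(
            {
                "sample_id": sample,
                "batch_id": bm.batch_map[sample],
                "m2": int(m2[sample]),
                "m1": m1,
                "entropy": band_entropy(int(m2[sample]), m1, cfg.C),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def fingerprint_entropy(areas) -> float:
    """Fingerprint entropy ``Sp = -sum_i a_i * ln(a_i / sum a)`` (>= 0).

    Peak areas act both as weights and, normalised, as the frequency inside
    the logarithm, so Sp carries the chromatogram's response scale. Zero-area
    peaks contribute 0 (the x ln x -> 0 limit); an all-zero vector has no
    defined entropy.
    """
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise EntropyDomainError("need at least one peak")
    if (a < 0).any():
        raise EntropyDomainError("peak areas must be non-negative")
    total = a.sum()
    if total == 0:
        raise EntropyDomainError("all-zero peak areas: entropy undefined")
    pos = a > 0
    f = a[pos] / total
    return float(-(a[pos] * np.log(f)).sum())


def batch_entropies_chemical(pt, batch_map: dict | pd.Series, cfg: HwepConfig = HwepConfig()) -> pd.DataFrame:
    """Per-sample fingerprint entropies of a PeakTable, mirroring the genetic frame.

    Columns: ``batch_id``, ``entropy``.
    """
    bmap = pd.Series(batch_map)
    areas = pt.areas if hasattr(pt, "areas") else pd.DataFrame(pt)
    rows = []
    for sample in areas.index:
        rows.append(
            {
                "sample_id": sample,
                "batch_id": bmap[sample],
                "entropy": fingerprint_entropy(areas.loc[sample].to_numpy()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def batch_rsd(values) -> float:
    """Relative standard deviation (sample sd over mean) as a fraction."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return 0.0  # identical values have no spread regardless of the mean
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined at zero mean")
    return float(sd / mean)


def hwep_size(rsd: float, cfg: HwepConfig = HwepConfig()) -> float:
    """HWEP size n from a batch RSD (fraction).

    ``table_consistent``: n = 100 * t_plus_u^2 * RSD^2 — equivalently
    (10.8 * RSD%)^2 / 100. ``eq5_literal``: n = K * RSD^2.
    """
    if rsd < 0:
        raise ValueError("RSD must be non-negative")
    if cfg.formula_mode == "eq5_literal":
        logger.warning(
            "eq5_literal mode (n = K * RSD^2) does not reproduce published "
            "batch tables; table_consistent is the validated default"
        )
        return cfg.K * rsd**2
    return 100.0 * cfg.t_plus_u**2 * rsd**2


def mqs(n: float, cfg: HwepConfig = HwepConfig()) -> float:
    """Minimum quantity for one sampling, in kg: n units of ``unit_mass_g``."""
    if n < 0:
        raise ValueError("HWEP size must be non-negative")
    return n * cfg.unit_mass_g / 1000.0


def batch_hwep_report(
    entropies: pd.DataFrame | dict, cfg: HwepConfig = HwepConfig()
) -> pd.DataFrame:
    """Per-batch RSD, HWEP size n and MQS from per-sample entropies.

    ``entropies`` is either the frame produced by
    :func:`batch_entropies_genetic` / :func:`batch_entropies_chemical`
    (columns ``batch_id`` and ``entropy``) or a mapping
    ``batch_id -> sequence of entropies``. Every batch needs >= 2 samples.
    Values are kept at full precision; see :func:`write_report` for the
    display-rounded table.
    """
    if isinstance(entropies, dict):
        groups = {b: np.asarray(v, dtype=float) for b, v in entropies.items()}
    else:
        groups = {
            b: g["entropy"].to_numpy()
            for b, g in entropies.groupby("batch_id", sort=False)
        }
    rows = []
    for batch, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
        rsd = batch_rsd(vals)
        n = hwep_size(rsd, cfg)
        rows.append(
            {
                "batch_id": batch,
                "n_samples": len(vals),
                "mean_entropy": float(np.mean(vals)),
                "RSD": rsd,
                "n": n,
                "MQS_kg": mqs(n, cfg),
            }
        )
    return pd.DataFrame(rows).set_index("batch_id")


def write_report(
    report: pd.DataFrame,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    cfg: HwepConfig = HwepConfig(),
) -> pd.DataFrame:
    """Emit the batch report rounded to display precision (CSV) and at full
    precision with the config block (JSON). Returns the rounded frame.

    Display precision: entropy 4 dp, RSD 2 dp percent, n 2 dp, MQS 3 dp kg.
    """
    disp = pd.DataFrame(
        {
            "n_samples": report["n_samples"],
            "mean_entropy": report["mean_entropy"].round(4),
            "RSD_percent": (100 * report["RSD"]).round(2),
            "n": report["n"].round(2),
            "MQS_kg": report["MQS_kg"].round(3),
        }
    )
    if csv_path is not None:
        disp.to_csv(csv_path, index_label="batch_id")
    if json_path is not None:
        payload = {
            "config": asdict(cfg),
            "batches": json.loads(report.to_json(orient="index")),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    return disp
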