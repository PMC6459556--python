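"""PT-IC-ddPCR absolute quantification.

A droplet digital PCR reaction partitions the template into ~20,000
droplets; template molecules distribute over droplets following Poisson
statistics, so the mean copies per droplet is recovered from the positive
fraction as

    lambda = -ln(1 - k/n)

and concentration (copies/µl) follows by dividing by the droplet volume.
The PT modification frequency at a locus is measured with a paired design:
an iodine-treated arm, where cleavage destroys modified template, yields X
(surviving, unmodified copies), and a mock-treated arm yields Y (total
copies).  The frequency is (Y - X)/Y.

Droplet volume defaults to 0.85 nl (QX200 nominal).  It cancels in
(Y - X)/Y when both arms share the same droplet geometry, but not in
copies/µl — change it if your instrument differs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_DROPLET_VOLUME_UL = 0.00085
DEFAULT_REACTION_VOLUME_UL = 20.0
DEFAULT_MIN_DROPLETS = 10_000


@dataclass
class DdpcrWell:
    """Droplet counts for one well."""

    well_id: str
    k: int  # positive droplets
    n: int  # total accepted droplets
    treatment: str = "mock"  # iodine | mock | NTC
    replicate: str = "1"
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL

    def __post_init__(self):
        if not (0 <= self.k <= self.n):
            raise ValueError(f"well {self.well_id}: need 0 <= k <= n, got k={self.k}, n={self.n}")
        if self.droplet_volume_ul <= 0 or self.reaction_volume_ul <= 0:
            raise ValueError(f"well {self.well_id}: volumes must be positive")


@dataclass
class DdpcrEstimate:
    """Poisson-inverted copy-number estimate for one well."""

    well: DdpcrWell
    lam: float  # mean copies per droplet
    conc: float  # copies per µl
    copies_total: float
    qc_pass: bool = True
    status: str = "ok"


@dataclass
class DdpcrAssay:
    """Paired iodine/mock result: frequency = (Y - X)/Y."""

    X: float  # mean conc of iodine-treated wells (unmodified survivors)
    Y: float  # mean conc of mock-treated wells (total)
    frequency_raw: float
    frequency: float
    clamped: bool
    n_wells_iodine: int
    n_wells_mock: int


class SaturatedWellError(ValueError):
    """All droplets positive: lambda is unbounded."""


def estimate_well(well: DdpcrWell) -> DdpcrEstimate:
    """Invert Poisson droplet occupancy to copies per droplet and per µl."""
    if well.n == 0:
        raise ValueError(f"well {well.well_id}: no accepted droplets")
    if well.k == well.n:
        raise SaturatedWellError(f"well {well.well_id}: saturated (all {well.n} droplets positive)")
    lam = -math.log(1.0 - well.k / well.n)
    conc = lam / well.droplet_volume_ul
    return DdpcrEstimate(well, lam, conc, conc * well.reaction_volume_ul)


def well_qc(well: DdpcrWell, min_droplets: int = DEFAULT_MIN_DROPLETS) -> bool:
    """Accept a well only with enough droplets; NTC wells never enter X/Y.

    NTC wells with positive droplets indicate contamination and are logged.
    """
    if well.treatment == "NTC":
        if well.k > 0:
            logger.warning("NTC well %s has %d positive droplets", well.well_id, well.k)
        return False
    return well.n >= min_droplets


def assay_frequency(
    wells: Sequence[DdpcrWell],
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    aggregate: str = "mean",
) -> DdpcrAssay:
    """PT frequency (Y - X)/Y from paired iodine/mock wells.

    X and Y are aggregated per-well concentrations over QC-passing
    replicates (mean by default, ``aggregate="median"`` for robustness).
    A negative raw frequency (noise near 0) clamps to 0 with a flag.
    """
    agg = np.median if aggregate == "median" else np.mean
    concs: dict[str, list[float]] = {"iodine": [], "mock": []}
    for w in wells:
        if not well_qc(w, min_droplets):
            continue
        if w.treatment in concs:
            concs[w.treatment].append(estimate_well(w).conc)
    if not concs["iodine"] or not concs["mock"]:
        missing = [t for t, c in concs.items() if not c]
        raise ValueError(f"no QC-passing wells for treatment arm(s): {missing}")
    X = float(agg(concs["iodine"]))
    Y = float(agg(concs["mock"]))
    if Y <= 0:
        raise ValueError("mock arm (total copies) is zero; frequency undefined")
    raw = (Y - X) / Y
    freq = min(max(raw, 0.0), 1.0)
    return DdpcrAssay(X, Y, raw, freq, clamped=(freq != raw),
                      n_wells_iodine=len(concs["iodine"]), n_wells_mock=len(concs["mock"]))


@dataclass
class StandardCurve:
    """OLS fit of measured vs expected concentration on log10(c + 1) axes."""

    slope: float
    intercept: float
    r_squared: float
    levels: list[dict]  # expected, mean, rsd_pct, rsd_pass per level


def standard_curve(
    levels: Sequence[tuple[float, Sequence[float]]],
    rsd_limit_pct: float = 25.0,
) -> StandardCurve:
    """Dilution-series linearity and precision diagnostics.

    ``levels`` pairs an expected concentration (copies/µl) with the
    replicate measured concentrations.  The regression uses
    log10(conc + 1) on both axes; per-level RSD% = 100*sd/mean is computed
    on the raw concentrations.
    """
    if len(levels) < 3:
        raise ValueError("standard curve needs at least 3 levels")
    x, y, info = [], [], []
    for expected, reps in levels:
        reps = np.asarray(list(reps), dtype=float)
        mean = float(reps.mean())
        sd = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
        rsd = 100.0 * sd / mean if mean > 0 else float("nan")
        info.append(
            {"expected": expected, "mean": mean, "rsd_pct": rsd, "rsd_pass": rsd < rsd_limit_pct}
        )
        for r in reps:
            x.append(math.log10(expected + 1.0))
            y.append(math.log10(r + 1.0))
    if np.ptp(x) == 0:
        raise ValueError("degenerate standard curve: all expected concentrations equal")
    fit = stats.linregress(x, y)
    return StandardCurve(fit.slope, fit.intercept, fit.rvalue**2, info)


def simulate_ddpcr(
    true_conc: float,
    n_droplets: int = 20_000,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    seed: int = 0,
    well_id: str = "sim",
    treatment: str = "mock",
) -> DdpcrWell:
    """Draw a synthetic well: droplets positive with p = 1 - exp(-c*v)."""
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    rng = np.random.default_rng(seed)
    p = 1.0 - math.exp(-true_conc * droplet_volume_ul)
    k = int(rng.binomial(n_droplets, p))
    return DdpcrWell(well_id, k, n_droplets, treatment=treatment,
                     droplet_volume_ul=droplet_volume_ul)


def read_wells_csv(path) -> list[DdpcrWell]:
    """Read wells from CSV: well_id, treatment, k, n[, replicate][, level]."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"well_id", "treatment", "k", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wells CSV missing columns: {sorted(missing)}")
    wells = []
    for _, row in df.iterrows():
        wells.append(
            DdpcrWell(
                well_id=str(row["well_id"]),
                k=int(row["k"]),
                n=int(row["n"]),
                treatment=str(row["treatment"]),
                replicate=str(row.get("replicate", "1")),
            )
        )
    return wells
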