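"""Stage 1 of the pipeline: measured peak tables → per-residue rates.

Converts peak-volume decay series into R1/R2 rates (mono-exponential
least-squares fits), saturated/reference intensity pairs into heteronuclear
NOEs, and TROSY/anti-TROSY intensity pairs into cross-correlated relaxation
rates η_xy = −ln(I^β/I^α)/(2Δ).  Also applies the cross-dataset error
regularisation used for CCR data (average the two datasets' σ, then floor
at 5 % relative) and computes combined ¹H/¹⁵N chemical-shift perturbations
Δδ_eff = √(Δδ_H² + (0.16 Δδ_N)²).

Tables travel as TSV/CSV with named columns; lines starting with ``#`` are
comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "NOEPair",
    "IntensityPair",
    "RelaxationTable",
    "CSPRecord",
    "fit_monoexponential",
    "compute_noe",
    "compute_etaxy",
    "regularize_ccr_errors",
    "compute_csp",
    "read_rate_table",
    "write_rate_table",
    "read_decay_tables",
    "write_decay_tables",
]

#: Default ¹H saturation time of the steady-state NOE experiment (s).
DEFAULT_NOE_SATURATION_S = 5.0

#: Default CCR relaxation delay (s): TROSY/anti-TROSY recorded at Δ = 0 and 10 ms.
DEFAULT_CCR_DELAY_S = 0.010


@dataclass
class DecaySeries:
    """A relaxation decay for one residue: (delay, volume, sigma) points.

    Duplicate delays are allowed and weighted as independent measurements.
    """

    residue: int
    delays: np.ndarray
    volumes: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.delays) == len(self.volumes) == len(self.sigmas)):
            raise ValueError("delay/volume/sigma arrays must have equal length")
        if len(np.unique(self.delays)) < 3:
            raise ValueError("a decay series needs at least 3 distinct delays")
        if not np.all(np.isfinite(self.volumes)):
            raise ValueError("volumes must be finite")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be positive")


@dataclass(frozen=True)
class NOEPair:
    """Saturated/reference intensity pair for one residue."""

    residue: int
    Isat: float
    Iref: float
    sigma_sat: float
    sigma_ref: float
    saturation_s: float = DEFAULT_NOE_SATURATION_S

    def __post_init__(self) -> None:
        if self.Iref == 0:
            raise ValueError("reference intensity must be nonzero")
        if self.sigma_sat <= 0 or self.sigma_ref <= 0:
            raise ValueError("base-plane noise estimates must be positive")


@dataclass(frozen=True)
class IntensityPair:
    """TROSY (I^α) / anti-TROSY (I^β) intensities at one relaxation delay."""

    residue: int
    Ialpha: float
    Ibeta: float
    Delta: float

    def __post_init__(self) -> None:
        if self.Delta < 0:
            raise ValueError("relaxation delay must be non-negative")


_RATE_FIELDS = ("R1", "R2", "NOE", "eta_xy")


@dataclass
class RelaxationTable:
    """Per-residue relaxation observables with one-SD uncertainties.

    ``data`` is indexed by residue number with columns drawn from
    R1, R1_err, R2, R2_err, NOE, NOE_err, eta_xy, eta_xy_err (missing
    observables are absent or NaN).  ``field_mhz`` records the spectrometer
    ¹H frequency the data were measured at.
    """

    data: pd.DataFrame
    field_mhz: float | None = None
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicated residue ids in relaxation table")
        for f in _RATE_FIELDS:
            if f in self.data.columns and f + "_err" not in self.data.columns:
                raise ValueError(f"column {f} present without {f}_err")

    @property
    def residues(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def ratio_r2r1(self) -> pd.DataFrame:
        """R2/R1 per residue with quadrature-propagated σ."""
        sub = self.data.dropna(subset=["R1", "R2"])
        ratio = sub["R2"] / sub["R1"]
        rel = np.sqrt(
            (sub["R2_err"] / sub["R2"]) ** 2 + (sub["R1_err"] / sub["R1"]) ** 2
        )
        return pd.DataFrame({"ratio": ratio, "ratio_err": ratio.abs() * rel})


@dataclass(frozen=True)
class CSPRecord:
    """Combined amide chemical-shift perturbation for one residue."""

    residue: int
    dH: float
    dN: float

    @property
    def ddEff(self) -> float:
        return math.sqrt(self.dH**2 + (0.16 * self.dN) ** 2)


def fit_monoexponential(series: DecaySeries, weighted: bool = False):
    """Fit A·exp(−R·t) to a decay; return (rate, sigma_rate, amplitude).

    Unweighted least squares by default (σ of the rate then comes from the
    covariance of the fit, scaled by the residual variance, which matches
    covariance-based error reporting); set ``weighted=True`` to use the
    per-point sigmas as weights.
    """

    def model(t, A, R):
        return A * np.exp(-R * t)

    t, y = series.delays, series.volumes
    span = t.max() - t.min()
    # crude initial slope from the endpoints in log space
    y0 = max(abs(y[np.argmin(t)]), 1e-300)
    y1 = max(abs(y[np.argmax(t)]), 1e-300)
    r0 = math.log(y0 / y1) / span if y0 > y1 else 1.0 / span
    p0 = (y[np.argmin(t)], max(r0, 1e-6))
    sigma = series.sigmas if weighted else None
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, sigma=sigma, absolute_sigma=weighted, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"decay fit failed for residue {series.residue}") from exc
    A, R = popt
    sigma_R = math.sqrt(max(pcov[1, 1], 0.0))
    return R, sigma_R, A


def compute_noe(pair: NOEPair) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat/I_ref with quadrature error propagation."""
    noe = pair.Isat / pair.Iref
    sigma = abs(noe) * math.sqrt(
        (pair.sigma_sat / pair.Isat) ** 2 + (pair.sigma_ref / pair.Iref) ** 2
    ) if pair.Isat != 0 else pair.sigma_sat / abs(pair.Iref)
    return noe, sigma


def compute_etaxy(
    pair: IntensityPair, zero_delay_pair: IntensityPair | None = None
) -> tuple[float, float]:
    """η_xy = −ln(I^β/I^α)/(2Δ), σ from the Δ=0 pair's α/β discrepancy.

    At Δ = 0 the TROSY and anti-TROSY intensities are nominally equal; their
    observed mismatch is used as a (crude, two-point) noise estimate that is
    propagated through the logarithm.
    """
    if pair.Delta <= 0:
        raise ValueError("rate pair must have a positive relaxation delay")
    if pair.Ialpha <= 0 or pair.Ibeta <= 0:
        raise ValueError("intensities must be positive for rate computation")
    eta = -math.log(pair.Ibeta / pair.Ialpha) / (2.0 * pair.Delta)
    sigma = float("nan")
    if zero_delay_pair is not None:
        i0 = 0.5 * (zero_delay_pair.Ialpha + zero_delay_pair.Ibeta)
        dI = abs(zero_delay_pair.Ialpha - zero_delay_pair.Ibeta) / math.sqrt(2.0)
        if i0 > 0 and dI > 0:
            # relative intensity noise enters both logs in quadrature
            sigma = math.sqrt(2.0) * (dI / i0) / (2.0 * pair.Delta)
    return eta, sigma


def regularize_ccr_errors(
    table_a: RelaxationTable, table_b: RelaxationTable, floor: float = 0.05
) -> RelaxationTable:
    """Average η_xy errors across two datasets, then floor at ``floor``·|η_xy|.

    The per-residue σ of ``table_a`` is replaced by the mean of the two
    datasets' σ where both are present, then regularised with a minimal
    relative error (default 5 %).  Returns a new table carrying table_a's
    values.  Idempotent when applied twice with the same partner.
    """
    common = table_a.data.index.intersection(table_b.data.index)
    if len(common) == 0:
        raise ValueError("no residues shared between the two CCR datasets")
    out = table_a.data.copy()
    mean_err = 0.5 * (
        table_a.data.loc[common, "eta_xy_err"] + table_b.data.loc[common, "eta_xy_err"]
    )
    out.loc[common, "eta_xy_err"] = mean_err
    floor_val = floor * out["eta_xy"].abs()
    out["eta_xy_err"] = np.maximum(out["eta_xy_err"], floor_val)
    prov = dict(table_a.provenance)
    prov["error_regularisation"] = f"cross-dataset mean, floored at {floor:.0%}"
    return RelaxationTable(out, field_mhz=table_a.field_mhz, provenance=prov)


def compute_csp(
    shifts_wt: pd.DataFrame, shifts_mut: pd.DataFrame
) -> list[CSPRecord]:
    """Combined CSPs between two variants.

    Both inputs are indexed by residue with columns ``H_ppm`` and ``N_ppm``.
    """
    common = shifts_wt.index.intersection(shifts_mut.index)
    if len(common) == 0:
        raise ValueError("no residues shared between the two shift tables")
    records = []
    for res in common:
        dH = float(shifts_mut.loc[res, "H_ppm"] - shifts_wt.loc[res, "H_ppm"])
        dN = float(shifts_mut.loc[res, "N_ppm"] - shifts_wt.loc[res, "N_ppm"])
        records.append(CSPRecord(residue=int(res), dH=dH, dN=dN))
    return records


# ---------------------------------------------------------------------------
# table I/O


def write_rate_table(table: RelaxationTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if table.field_mhz is not None:
            fh.write(f"# field_mhz = {table.field_mhz!r}\n")
        for k, v in table.provenance.items():
            fh.write(f"# {k} = {v}\n")
        table.data.rename_axis("residue").reset_index().to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_rate_table(path: str | Path) -> RelaxationTable:
    path = Path(path)
    field_mhz = None
    provenance: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = (s.strip() for s in body.split("=", 1))
                if k == "field_mhz":
                    field_mhz = float(v)
                else:
                    provenance[k] = v
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValueError(f"malformed rate table {path}: {exc}") from exc
    if "residue" not in df.columns:
        raise ValueError(f"{path}: missing required 'residue' column")
    for f in _RATE_FIELDS:
        if f in df.columns and f + "_err" not in df.columns:
            raise ValueError(f"{path}: column {f} present without its {f}_err column")
    df = df.set_index("residue")
    return RelaxationTable(df, field_mhz=field_mhz, provenance=provenance)


def write_decay_tables(series: Iterable[DecaySeries], path: str | Path) -> None:
    """Write a long-format TSV (residue, delay_s, volume, sigma)."""
    rows = []
    for s in series:
        for t, v, sg in zip(s.delays, s.volumes, s.sigmas):
            rows.append((s.residue, t, v, sg))
    pd.DataFrame(rows, columns=["residue", "delay_s", "volume", "sigma"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_decay_tables(path: str | Path) -> list[DecaySeries]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue", "delay_s", "volume", "sigma"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for res, grp in df.groupby("residue", sort=True):
        out.append(
            DecaySeries(
                residue=int(res),
                delays=grp["delay_s"].to_numpy(),
                volumes=grp["volume"].to_numpy(),
                sigmas=grp["sigma"].to_numpy(),
            )
        )
    return out
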