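"""Reading and writing titration data and fit reports.

Titration files are delimited text (CSV by default, TSV on request) with one
row per well.  Required columns: ``conc_mol_per_L`` (the column name enforces
the unit) and ``signal``.  Optional grouping columns ``antigen``, ``isotype``,
``dilution`` split the file into series; an optional ``replicate`` column
pivots repeated concentrations into replicate columns.  Zero or negative
concentrations are split out as blank wells (ln 0 is undefined) and logged.

Reports are one row per (series, model) with every fitted parameter, its
standard error and confidence interval, goodness-of-fit statistics and the
thermodynamic descriptors of Richards fits, written with 17 significant
digits so every float round-trips exactly.
"""

from __future__ import annotations

import json
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import BootstrapResult, FitResult, ModelKind, TitrationSeries
from .thermo import DerivedQuantities

__all__ = ["read_titration", "write_titration", "write_report", "read_report"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

_REQUIRED = ("conc_mol_per_L", "signal")
_GROUP_COLS = ("antigen", "isotype", "dilution")
_PARAM_UNION = (
    "s_floor",
    "s_span",
    "rate",
    "log_infl",
    "nu",
    "slope_b",
    "c_mid",
    "asym_g",
)
_FLOAT_FMT = "%.17g"


def _delimiter(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'tsv')")


def read_titration(path, dialect: str = "csv") -> list[TitrationSeries]:
    """Read a delimited titration file into one series per metadata group.

    Rows are grouped by whichever of ``antigen``/``isotype``/``dilution``
    columns are present, sorted by concentration within each group; blanks
    (conc <= 0) are split out with a logged count.
    """
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str, comment="#")
    df.columns = [c.strip() for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    for col in ("conc_mol_per_L", "signal"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +header +1-based
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} in column {col!r} "
                f"at line {row} of {path}"
            )
        if num.isna().any():
            row = int(np.nonzero(num.isna().to_numpy())[0][0]) + 2
            raise ValueError(f"empty value in column {col!r} at line {row} of {path}")
        # convert via Python float(): correctly rounded, so 17-digit output
        # round-trips bit-exactly (pandas' fast parser is off by 1 ulp)
        df[col] = raw.map(float)

    group_cols = [c for c in _GROUP_COLS if c in df.columns]
    groups = df.groupby(group_cols, dropna=False, sort=True) if group_cols else [((), df)]
    series_list = []
    for key, g in groups:
        meta = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        blanks = g[g["conc_mol_per_L"] <= 0]
        g = g[g["conc_mol_per_L"] > 0].sort_values("conc_mol_per_L", kind="mergesort")
        if len(blanks):
            logger.info(
                "series %s: %d blank (conc <= 0) wells split out", meta or "-", len(blanks)
            )
        if "replicate" in g.columns and g["replicate"].notna().any():
            wide = g.pivot_table(
                index="conc_mol_per_L", columns="replicate", values="signal", sort=True
            )
            if wide.isna().any().any():
                raise ValueError(
                    f"unbalanced replicates for series {meta or '-'}: every "
                    "concentration must appear in every replicate"
                )
            conc = wide.index.to_numpy(dtype=float)
            signal = wide.to_numpy(dtype=float)
            if signal.shape[1] == 1:
                signal = signal[:, 0]
        else:
            conc = g["conc_mol_per_L"].to_numpy(dtype=float)
            if np.unique(conc).size != conc.size:
                raise ValueError(
                    f"duplicate concentrations in series {meta or '-'}; "
                    "add a 'replicate' column to disambiguate"
                )
            signal = g["signal"].to_numpy(dtype=float)
        series_list.append(
            TitrationSeries(
                conc=conc,
                signal=signal,
                meta=meta,
                blank_signal=blanks["signal"].to_numpy(dtype=float) if len(blanks) else None,
            )
        )
    return series_list


def write_titration(series_list: Sequence[TitrationSeries], path, dialect: str = "csv") -> None:
    """Write series in the long format :func:`read_titration` reads back."""
    if isinstance(series_list, TitrationSeries):
        series_list = [series_list]
    rows = []
    for s in series_list:
        base = {c: s.meta.get(c) for c in _GROUP_COLS}
        sig2d = s.signal[:, None] if s.signal.ndim == 1 else s.signal
        for j in range(sig2d.shape[1]):
            for c, y in zip(s.conc, sig2d[:, j]):
                rows.append({**base, "replicate": j + 1, "conc_mol_per_L": c, "signal": y})
        if s.blank_signal is not None:
            for y in s.blank_signal:
                rows.append({**base, "replicate": 1, "conc_mol_per_L": 0.0, "signal": y})
    df = pd.DataFrame(rows, columns=[*_GROUP_COLS, "replicate", "conc_mol_per_L", "signal"])
    df.to_csv(path, sep=_delimiter(dialect), index=False, float_format=_FLOAT_FMT)


def _report_rows(
    fits: Sequence[FitResult],
    derived: Optional[Sequence[Optional[DerivedQuantities]]] = None,
    cis: Optional[Sequence[Optional[BootstrapResult]]] = None,
) -> pd.DataFrame:
    if not fits:
        raise ValueError("no fits to report")
    derived = derived if derived is not None else [None] * len(fits)
    cis = cis if cis is not None else [None] * len(fits)
    rows = []
    for fit, dq, ci in zip(fits, derived, cis):
        row: dict = {c: fit.series_meta.get(c) for c in _GROUP_COLS}
        row.update(
            model=fit.model.value,
            n_obs=fit.n_obs,
            converged=fit.converged,
            rss=fit.rss,
            aic=fit.aic,
            bic=fit.bic,
            r_squared=fit.r_squared,
        )
        values = {name: np.nan for name in _PARAM_UNION}
        ses = {name: np.nan for name in _PARAM_UNION}
        los = {name: np.nan for name in _PARAM_UNION}
        his = {name: np.nan for name in _PARAM_UNION}
        p = fit.params
        for name in _PARAM_UNION:
            if hasattr(p, name):
                values[name] = getattr(p, name)
        for i, name in enumerate(fit.param_names):
            key = "c_mid" if name == "log_c_mid" else name
            ses[key] = float(fit.param_se[i])
            if ci is not None:
                lo, hi = float(ci.lo[i]), float(ci.hi[i])
                if name == "log_c_mid":
                    lo, hi = np.exp(lo), np.exp(hi)
                los[key], his[key] = lo, hi
        for name in _PARAM_UNION:
            row[name] = values[name]
            row[f"se_{name}"] = ses[name]
            row[f"ci_lo_{name}"] = los[name]
            row[f"ci_hi_{name}"] = his[name]
        row["ag_infl_mol_per_L"] = dq.ag_infl if dq else np.nan
        row["kd_apparent_mol_per_L"] = dq.kd_apparent if dq else np.nan
        row["delta_mu_standard_kJ_per_mol"] = (
            dq.delta_mu_standard / 1000.0 if dq else np.nan
        )
        row["gamma_inf"] = dq.gamma_inf if dq else np.nan
        row["temperature_K"] = dq.temperature if dq else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    num = df.select_dtypes(include=[float])
    for col in num.columns:
        # derived/CI columns are legitimately absent for some models; only
        # unexpected non-finite core statistics warrant a warning
        if col in ("rss", "aic", "bic", "r_squared") and not np.isfinite(num[col]).all():
            for i in np.nonzero(~np.isfinite(num[col].to_numpy()))[0]:
                logger.warning(
                    "non-finite %s for series %s (model %s)",
                    col,
                    {c: df[c].iloc[i] for c in _GROUP_COLS},
                    df["model"].iloc[i],
                )
    return df


def write_report(
    fits: Sequence[FitResult],
    derived: Optional[Sequence[Optional[DerivedQuantities]]] = None,
    path=None,
    format: str = "csv",
    cis: Optional[Sequence[Optional[BootstrapResult]]] = None,
) -> pd.DataFrame:
    """Write one report row per fit; returns the report frame.

    CSV uses 17-significant-digit floats (lossless round trip); JSON wraps
    the same rows with a schema version.
    """
    df = _report_rows(fits, derived, cis)
    if path is not None:
        if format == "csv":
            df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        elif format == "json":
            payload = {
                "schema_version": REPORT_SCHEMA_VERSION,
                "rows": df.to_dict(orient="records"),
            }
            with open(path, "w") as fh:
                # stdlib json prints floats with repr -> lossless round trip
                json.dump(payload, fh, indent=1, default=lambda o: o.item())
                fh.write("\n")
        else:
            raise ValueError(f"unknown report format {format!r}")
    return df


def read_report(path, format: str = "csv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"])
    raise ValueError(f"unknown report format {format!r}")
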