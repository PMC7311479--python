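"""Stability-table reports: per-condition fits plus paired deltas.

``run_stability_report`` reproduces the layout of a published stability table:
one row per (protein, Ca2+ state, redox condition) with the fitted apparent Tm
or (dG_H2O, Cmid, m), and one row per reducing/nitrosylating pair with the
difference (dTm or ddG_H2O) and its quadrature-propagated standard error.
Rounded report columns use 1 decimal for degrees C and 2 decimals for kcal/mol
and M; full precision is kept in the unrounded columns so downstream arithmetic
never works from rounded numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import denaturation, thermal
from .denaturation import TwoStateFit, fit_two_state_global
from .thermal import BoltzmannFit, fit_boltzmann

log = logging.getLogger("lumistab")

__all__ = ["RunConfig", "run_stability_report", "melt_report", "denaturation_report"]


@dataclass
class RunConfig:
    """Manifest-driven run description (parsed from a YAML config)."""

    melt_files: list[dict] = field(default_factory=list)
    denat_files: list[dict] = field(default_factory=list)
    output_dir: Path = Path(".")
    temperature_K: float = denaturation.DEFAULT_TEMPERATURE_K
    se_mode: str = "global_covariance"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            melt_files=raw.get("melt_files", []),
            denat_files=raw.get("denat_files", []),
            output_dir=Path(raw.get("output_dir", ".")),
            temperature_K=float(raw.get("temperature_K", denaturation.DEFAULT_TEMPERATURE_K)),
            se_mode=raw.get("se_mode", "global_covariance"),
            seed=int(raw.get("seed", 0)),
        )
        for entry in cfg.melt_files + cfg.denat_files:
            p = Path(entry["path"])
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        return cfg


def melt_report(fits: Sequence[BoltzmannFit]) -> pd.DataFrame:
    """Per-melt rows plus rounded display columns (1 decimal for degrees C)."""
    rows = [f.as_row() for f in fits]
    df = pd.DataFrame(rows)
    df["apparent_tm_C_rounded"] = df["apparent_tm_C"].round(1)
    df["se_tm_C_rounded"] = df["se_tm_C"].round(1)
    return df


def denaturation_report(fits: Sequence[TwoStateFit]) -> pd.DataFrame:
    """Per-condition rows plus rounded display columns (2 decimals)."""
    rows = [f.as_row() for f in fits]
    df = pd.DataFrame(rows)
    for col in ("dg_h2o_kcal_mol", "se_dg_kcal_mol", "cmid_M",
                "m_value_kcal_mol_M", "se_m_kcal_mol_M"):
        df[col + "_rounded"] = df[col].round(2)
    return df


def _pair_deltas(fits, key_fn, delta_fn, value_name):
    """Pair reducing vs nitrosylating fits sharing (protein/ca_state) keys."""
    by_key: dict = {}
    for f in fits:
        by_key.setdefault(key_fn(f), {})[f.condition] = f
    rows = []
    for key, conds in sorted(by_key.items()):
        if "reducing" in conds and "nitrosylating" in conds:
            d = delta_fn(conds["reducing"], conds["nitrosylating"])
            rows.append({
                "group": "/".join(str(k) for k in key),
                f"{value_name}": d.value,
                f"se_{value_name}": d.error,
                f"{value_name}_rounded": round(d.value, 1 if value_name == "delta_tm_C" else 2),
                f"se_{value_name}_rounded": round(d.error, 1 if value_name == "delta_tm_C" else 2),
            })
    return pd.DataFrame(rows)


def run_stability_report(config: RunConfig) -> dict[str, pd.DataFrame]:
    """End-to-end stability report from a manifest config.

    Fits every melt file and every denaturation file (grouped replicates),
    then pairs reducing/nitrosylating conditions into delta rows. Fit failures
    are logged per row and the run continues. Deterministic for fixed inputs.
    Returns the report frames and writes them as CSV under ``output_dir``.
    """
    if not config.melt_files and not config.denat_files:
        raise ValueError("empty manifest: no melt or denaturation inputs")

    melt_fits: list[BoltzmannFit] = []
    for entry in config.melt_files:
        curve = thermal.read_melt_curve(
            entry["path"],
            protein_id=entry.get("protein", ""),
            condition=entry.get("condition", "reducing"),
            ca_state=entry.get("ca_state", "loaded"),
        )
        try:
            melt_fits.append(fit_boltzmann(curve))
            log.info("fit melt %s", entry["path"])
        except RuntimeError as exc:
            log.error("melt fit failed for %s: %s", entry["path"], exc)

    denat_fits: list[TwoStateFit] = []
    for entry in config.denat_files:
        curves = denaturation.read_denaturation_curves(
            entry["path"],
            condition=entry.get("condition", "reducing"),
            ca_state=entry.get("ca_state", "depleted"),
        )
        try:
            denat_fits.append(
                fit_two_state_global(
                    curves, temperature=config.temperature_K, se_mode=config.se_mode
                )
            )
            log.info("fit denaturation %s (%d replicates)", entry["path"], len(curves))
        except RuntimeError as exc:
            log.error("denaturation fit failed for %s: %s", entry["path"], exc)

    out: dict[str, pd.DataFrame] = {}
    if melt_fits:
        out["melts"] = melt_report(melt_fits)
        out["delta_tm"] = _pair_deltas(
            melt_fits, lambda f: (f.protein_id, f.ca_state),
            thermal.delta_tm, "delta_tm_C",
        )
    if denat_fits:
        out["denaturation"] = denaturation_report(denat_fits)
        out["delta_delta_g"] = _pair_deltas(
            denat_fits, lambda f: (f.ca_state,),
            denaturation.delta_delta_g, "ddg_kcal_mol",
        )

    config.output_dir.mkdir(parents=True, exist_ok=True)
    for name, df in out.items():
        path = config.output_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        log.info("wrote %s", path)
    return out
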