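"""Readers/writers for the pipeline's tab-separated tables.

One dialect everywhere: TSV with a header row, UTF-8, no quoting.
Positions are 1-based and treated as opaque labels (only MI matters to
the analyses).  Errors name the offending column or 1-based file line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .regression import MIBin, RegressionFit
from .synthetic import DNMDataset, MISiteTrack, TwoSpeciesSNPTable

__all__ = [
    "PipelineConfig",
    "read_dnm_table", "write_dnm_table",
    "read_mi_track", "write_mi_track",
    "read_snp_table", "write_snp_table",
    "read_bins", "write_bins",
    "read_fit", "write_fit",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline defaults (bin width 10, drop bins with <=5 DNMs, 1000
    simulation replicates, divergences 0.0092 non-CpG / 0.092 CpG)."""

    seed: int = 0
    log_base: float = 10.0
    bin_width: int = 10
    min_dnm: int = 5
    weighting: str = "expected"
    divergence_cpg: float = 0.092
    divergence_non_cpg: float = 0.0092
    upsilons: Sequence[float] = (
        0, 1_000, 10_000, 100_000, 500_000,
        1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000,
    )
    n_reps: int = 1000
    out_dir: str = "."


def _read_tsv(path, required: Sequence[str], int_cols: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    for col in int_cols:
        try:
            frame[col] = frame[col].astype(np.int64)
        except (TypeError, ValueError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = int(bad[bad.isna() | (bad != bad.round())].index[0])
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"{path}: non-integer value {frame[col].iloc[row]!r} in column "
                f"'{col}' at line {row + 2}"
            ) from None
    return frame


def read_dnm_table(path) -> DNMDataset:
    frame = _read_tsv(path, required=("chrom", "pos", "mi"), int_cols=("pos", "mi"))
    if "study" not in frame.columns:
        frame["study"] = ""
    return DNMDataset(frame[["chrom", "pos", "mi", "study"]])


def write_dnm_table(dnms: DNMDataset, path) -> None:
    dnms.frame.to_csv(path, sep="\t", index=False)


def read_mi_track(path) -> MISiteTrack:
    frame = _read_tsv(path, required=("mi", "n_sites"), int_cols=("mi", "n_sites"))
    dup = frame["mi"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate MI value {int(frame['mi'][dup].iloc[0])} "
            f"at line {int(dup.idxmax()) + 2}"
        )
    return MISiteTrack(mi=frame["mi"].to_numpy(), n_sites=frame["n_sites"].to_numpy())


def write_mi_track(track: MISiteTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> TwoSpeciesSNPTable:
    frame = _read_tsv(path, required=("site_id", "is_cpg", "snp_a", "snp_b"),
                      int_cols=("site_id",))
    for col in ("is_cpg", "snp_a", "snp_b"):
        frame[col] = frame[col].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
        if frame[col].isna().any():
            raise ValueError(f"{path}: column '{col}' must be boolean (0/1/True/False)")
        frame[col] = frame[col].astype(bool)
    if "gamma_true" in frame.columns:
        frame["gamma_true"] = frame["gamma_true"].replace("", np.nan).astype(float)
    if "mi" in frame.columns:
        frame["mi"] = frame["mi"].replace("", np.nan).astype(float)
    return TwoSpeciesSNPTable(frame)


def write_snp_table(table: TwoSpeciesSNPTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_bins(path) -> List[MIBin]:
    frame = pd.read_csv(path, sep="\t")
    for col in ("mi_mid", "n", "d"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return [
        MIBin(mi_mid=float(r.mi_mid), n=int(r.n), d=int(r.d))
        for r in frame.itertuples()
    ]


def write_bins(bins: Sequence[MIBin], path) -> None:
    pd.DataFrame(
        {
            "mi_mid": [b.mi_mid for b in bins],
            "n": [b.n for b in bins],
            "d": [b.d for b in bins],
            "z": [b.z for b in bins],
        }
    ).to_csv(path, sep="\t", index=False)


_FIT_FIELDS = ("slope", "intercept", "se_slope", "se_intercept",
               "log_base", "r", "quad_coeff", "quad_p")


def write_fit(fit: RegressionFit, path) -> None:
    """Serialize a fit as a flat key<TAB>value block."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in _FIT_FIELDS:
            value = getattr(fit, name)
            if value is not None:
                fh.write(f"{name}\t{value!r}\n")
        fh.write(f"degenerate\t{fit.degenerate}\n")
        fh.write(f"weighting\t{fit.weighting}\n")


def read_fit(path) -> RegressionFit:
    values = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                key, _, raw = line.rstrip("\n").partition("\t")
                values[key] = raw
    kwargs = {}
    for name in _FIT_FIELDS:
        if name in values:
            kwargs[name] = float(values[name])
    kwargs["degenerate"] = values.get("degenerate", "False") == "True"
    kwargs["weighting"] = values.get("weighting", "expected")
    return RegressionFit(**kwargs)
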