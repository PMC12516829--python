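"""CSV dialects shared by the pipeline stages.

Assay records travel as one row per measurement with the compound-level
fields repeated: ``compound_id, smiles, ph, solubility_uM`` (or
``log_s_molar``), ``solid_state, censored, is_salt, acidic_pkas, basic_pkas,
replicate_spread``.  pKa lists are semicolon-separated.  Solubilities are
converted to log10 molar at this boundary; everything downstream is log
molar.  A missing ``censored`` column is inferred from the assay window.
"""

from __future__ import annotations

import math

import pandas as pd

from .curation import (
    Censoring,
    CompoundEntry,
    CurationConfig,
    SolidState,
    SolubilityRecord,
    TaskTable,
)
from .speciation import IonizationModel

__all__ = ["read_records_csv", "write_records_csv", "write_s0_csv",
           "read_s0_csv", "write_task_table_csv", "read_task_table_csv"]


def _parse_pkas(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    s = str(cell).strip()
    if not s:
        return ()
    return tuple(float(x) for x in s.split(";") if x.strip())


def _fmt_pkas(pkas) -> str:
    return ";".join(f"{p:.6g}" for p in pkas)


def read_records_csv(
    path, config: CurationConfig | None = None
) -> tuple[list[CompoundEntry], list[SolubilityRecord]]:
    """Load the assay-record dialect into entries + records.

    Raises ValueError naming the first missing required column.
    """
    config = config or CurationConfig()
    df = pd.read_csv(path)
    required = ["compound_id", "smiles", "ph", "solid_state", "is_salt",
                "acidic_pkas", "basic_pkas"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    if "log_s_molar" not in df.columns and "solubility_uM" not in df.columns:
        raise ValueError("missing required column: 'log_s_molar' or 'solubility_uM'")

    lo, hi = config.log_window
    entries: dict[str, CompoundEntry] = {}
    records: list[SolubilityRecord] = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        if cid not in entries:
            entries[cid] = CompoundEntry(
                compound_id=cid,
                smiles=str(row["smiles"]),
                ionization=IonizationModel(
                    acidic_pkas=_parse_pkas(row["acidic_pkas"]),
                    basic_pkas=_parse_pkas(row["basic_pkas"]),
                ),
                is_salt=bool(int(row["is_salt"])),
            )
        if "log_s_molar" in df.columns and not pd.isna(row["log_s_molar"]):
            log_s = float(row["log_s_molar"])
        else:
            log_s = math.log10(float(row["solubility_uM"]) * 1e-6)
        if "censored" in df.columns and not pd.isna(row["censored"]):
            cens = Censoring(str(row["censored"]))
        elif log_s <= lo:
            cens = Censoring.below_lo
        elif log_s >= hi:
            cens = Censoring.above_hi
        else:
            cens = Censoring.none
        records.append(SolubilityRecord(
            compound_id=cid,
            ph=float(row["ph"]),
            log_s=log_s,
            solid_state=SolidState(str(row["solid_state"])),
            censored=cens,
            replicate_spread=float(row.get("replicate_spread", 0.0) or 0.0)
            if "replicate_spread" in df.columns else 0.0,
        ))
    return list(entries.values()), records


def write_records_csv(path, entries, records):
    emap = {e.compound_id: e for e in entries}
    rows = []
    for r in records:
        e = emap[r.compound_id]
        rows.append({
            "compound_id": r.compound_id,
            "smiles": e.smiles,
            "ph": r.ph,
            "log_s_molar": r.log_s,
            "solubility_uM": 10.0 ** r.log_s / 1e-6,
            "solid_state": r.solid_state.value,
            "censored": r.censored.value,
            "is_salt": int(e.is_salt),
            "acidic_pkas": _fmt_pkas(e.ionization.acidic_pkas),
            "basic_pkas": _fmt_pkas(e.ionization.basic_pkas),
            "replicate_spread": r.replicate_spread,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_s0_csv(path, s0_frame: pd.DataFrame):
    """Curated S0 output: compound_id, smiles, log_s0_molar, high_quality."""
    out = s0_frame[s0_frame["status"] == "ok"][
        ["compound_id", "smiles", "log_s0", "high_quality"]
    ].rename(columns={"log_s0": "log_s0_molar"})
    out = out.assign(high_quality=out["high_quality"].astype(int))
    out.to_csv(path, index=False)


def read_s0_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("compound_id", "smiles", "log_s0_molar", "high_quality"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    return df


def write_task_table_csv(path, table: TaskTable):
    table.to_frame().to_csv(path, index=False)


def read_task_table_csv(path) -> TaskTable:
    return TaskTable.from_frame(pd.read_csv(path))
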