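"""Curation of pH-dependent solubility assays into an intrinsic-solubility dataset.

The raw input is one record per assay measurement (pH 2 / pH 7 high-throughput
solubility with a solid-state readout of the residual solid) plus, per
compound, predicted acidic and basic pKa lists.  Curation applies, in order:

1. keep only crystalline, uncensored records of non-salt compounds;
2. pick the derivation condition per compound from its ionization type
   (acid-only -> pH 2, base-only -> pH 7, ordinary ampholyte -> the pH closest
   to the midpoint of min(acidic pKa) and max(basic pKa), zwitterion-like
   gap <= 2 -> discard, no pKa -> the measurement is S0 directly);
3. invert the speciation map at the chosen pH using the relevant pKa subset;
4. merge replicate-derived S0 values: retained only when they agree within
   0.7 log units, taking the smaller value (more stable polymorph);
5. flag the high-quality subset (crystalline, uncensored, replicate spread
   below tolerance), used downstream for stratified splitting and test-set
   evaluation.

The eight-task training table (S0 plus pH 2 / pH 7 / FaSSIF solubility, logP,
and logD at three pHs) is assembled as a sparse compound-by-task matrix with
an observation mask; missing values are never imputed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .speciation import (
    MAX_RELEVANT_PKAS,
    DEFAULT_FRACTION_THRESHOLD,
    IonizationModel,
    intrinsic_from_measured,
    relevant_pkas,
)

__all__ = [
    "SolidState",
    "Censoring",
    "SolubilityRecord",
    "CompoundEntry",
    "CurationConfig",
    "Selection",
    "TaskTable",
    "TASK_NAMES",
    "filter_records",
    "select_derivation_record",
    "derive_s0",
    "merge_duplicates",
    "flag_high_quality",
    "build_task_table",
    "curate_s0",
]

TASK_NAMES = (
    "S0",
    "sol_pH2",
    "sol_pH7",
    "sol_fassif",
    "logP",
    "logD_2.6",
    "logD_7.4",
    "logD_10.5",
)


class SolidState(str, enum.Enum):
    crystalline = "crystalline"
    amorphous = "amorphous"
    unknown = "unknown"


class Censoring(str, enum.Enum):
    none = "none"
    below_lo = "below_lo"
    above_hi = "above_hi"


@dataclass(frozen=True)
class SolubilityRecord:
    """One assay measurement: log10 molar solubility at a given pH."""

    compound_id: str
    ph: float
    log_s: float
    solid_state: SolidState = SolidState.unknown
    censored: Censoring = Censoring.none
    replicate_spread: float = 0.0  # max pairwise replicate difference, log units


@dataclass(frozen=True)
class CompoundEntry:
    compound_id: str
    smiles: str
    ionization: IonizationModel
    is_salt: bool = False


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the curation rules (log units / pH units / molar)."""

    duplicate_threshold: float = 0.7      # log units; replicate agreement
    zwitterion_gap: float = 2.0           # pH units; min(acidic)-max(basic)
    assay_lo_uM: float = 0.1              # assay floor
    assay_hi_uM: float = 600.0            # assay ceiling
    max_relevant_pkas: int = MAX_RELEVANT_PKAS
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD
    hq_spread_tolerance: float = 0.5      # log units; high-quality flag

    def __post_init__(self):
        for name in ("duplicate_threshold", "zwitterion_gap", "assay_lo_uM",
                     "assay_hi_uM", "hq_spread_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def log_window(self) -> tuple[float, float]:
        """Assay dynamic range in log10 molar units."""
        return (math.log10(self.assay_lo_uM * 1e-6),
                math.log10(self.assay_hi_uM * 1e-6))


@dataclass(frozen=True)
class Selection:
    """Outcome of the derivation-condition choice for one compound."""

    status: str                      # 'chosen' | 'direct' | 'discard'
    ph: float | None = None
    records: tuple[SolubilityRecord, ...] = ()
    reason: str = ""


def filter_records(
    records: list[SolubilityRecord],
    config: CurationConfig,
    entries: dict[str, CompoundEntry] | None = None,
) -> list[SolubilityRecord]:
    """Crystalline, uncensored records of non-salt compounds, order preserved."""
    out = []
    for r in records:
        if r.solid_state is not SolidState.crystalline:
            continue
        if r.censored is not Censoring.none:
            continue
        if entries is not None:
            e = entries.get(r.compound_id)
            if e is not None and e.is_salt:
                continue
        out.append(r)
    return out


def _records_at(records, ph, tol=1e-6):
    return tuple(r for r in records if abs(r.ph - ph) <= tol)


def select_derivation_record(
    entry: CompoundEntry,
    records: list[SolubilityRecord],
    config: CurationConfig | None = None,
) -> Selection:
    """Apply the per-class derivation rules to one compound's filtered records.

    Returns the record set at the chosen pH ('chosen'), all records for
    no-pKa compounds ('direct'), or a 'discard' with a reason code.
    """
    config = config or CurationConfig()
    model = entry.ionization
    if not records:
        return Selection(status="discard", reason="no_records")

    kind = model.kind
    if kind == "neutral":
        return Selection(status="direct", records=tuple(records))

    if kind == "acid":
        target_ph = 2.0
    elif kind == "base":
        target_ph = 7.0
    else:  # amphoteric: zwitterion gap rule, then midpoint
        gap = min(model.acidic_pkas) - max(model.basic_pkas)
        if gap <= config.zwitterion_gap:
            return Selection(status="discard", reason="zwitterion")
        midpoint = (min(model.acidic_pkas) + max(model.basic_pkas)) / 2.0
        phs = sorted({r.ph for r in records})
        target_ph = min(phs, key=lambda p: (abs(p - midpoint), p))

    chosen = _records_at(records, target_ph)
    if not chosen:
        return Selection(status="discard", reason=f"missing_ph{target_ph:g}")

    _, n_rel = relevant_pkas(model, target_ph, config.fraction_threshold)
    if n_rel > config.max_relevant_pkas:
        return Selection(status="discard", reason="too_many_relevant_pkas")
    return Selection(status="chosen", ph=target_ph, records=chosen)


def derive_s0(
    entry: CompoundEntry,
    record: SolubilityRecord,
    config: CurationConfig | None = None,
) -> float:
    """log10 molar S0 from one chosen record.

    No-pKa compounds take the measurement directly; otherwise the speciation
    map is inverted with the relevant pKa subset at the record's pH.
    """
    config = config or CurationConfig()
    if entry.ionization.n_pkas == 0:
        return record.log_s
    rel_model, _ = relevant_pkas(
        entry.ionization, record.ph, config.fraction_threshold
    )
    return intrinsic_from_measured(record.log_s, rel_model, record.ph)


def merge_duplicates(
    s0_values: list[float], config: CurationConfig | None = None
) -> float | None:
    """Replicate rule: retain min(S0) when the spread is < threshold, else drop.

    Returns None when the values disagree (spread >= 0.7 log units by default),
    mirroring the exclusion of irreproducible duplicates.
    """
    config = config or CurationConfig()
    if not s0_values:
        raise ValueError("merge_duplicates needs at least one value")
    if len(s0_values) == 1:
        return s0_values[0]
    if max(s0_values) - min(s0_values) < config.duplicate_threshold:
        return min(s0_values)
    return None


def flag_high_quality(
    records: list[SolubilityRecord],
    tolerance: float = 0.5,
) -> bool:
    """High-quality flag: crystalline, uncensored, replicate spread <= tolerance.

    Applied to the derivation records of a compound; any failing record
    disqualifies the compound.
    """
    if not records:
        return False
    return all(
        r.solid_state is SolidState.crystalline
        and r.censored is Censoring.none
        and r.replicate_spread <= tolerance
        for r in records
    )


def curate_s0(
    entries: list[CompoundEntry],
    records: list[SolubilityRecord],
    config: CurationConfig | None = None,
) -> pd.DataFrame:
    """Full S0 pipeline: filter, select, derive, merge, flag.

    Returns a DataFrame with one row per input compound: compound_id, smiles,
    status ('ok' or a discard reason), log_s0 (NaN when discarded) and
    high_quality (bool).  Deterministic and independent of input ordering.
    """
    config = config or CurationConfig()
    entry_map = {e.compound_id: e for e in entries}
    kept = filter_records(records, config, entries=entry_map)
    by_compound: dict[str, list[SolubilityRecord]] = {}
    for r in kept:
        by_compound.setdefault(r.compound_id, []).append(r)

    rows = []
    for e in sorted(entries, key=lambda e: e.compound_id):
        recs = by_compound.get(e.compound_id, [])
        if e.is_salt:
            rows.append((e.compound_id, e.smiles, "salt", np.nan, False))
            continue
        sel = select_derivation_record(e, recs, config)
        if sel.status == "discard":
            rows.append((e.compound_id, e.smiles, sel.reason, np.nan, False))
            continue
        values = [derive_s0(e, r, config) for r in sel.records]
        merged = merge_duplicates(values, config)
        if merged is None:
            rows.append(
                (e.compound_id, e.smiles, "duplicate_disagreement", np.nan, False)
            )
            continue
        hq = flag_high_quality(list(sel.records), config.hq_spread_tolerance)
        rows.append((e.compound_id, e.smiles, "ok", merged, hq))
    return pd.DataFrame(
        rows, columns=["compound_id", "smiles", "status", "log_s0", "high_quality"]
    )


@dataclass
class TaskTable:
    """Sparse compound-by-task target matrix with observation mask."""

    compound_ids: list[str]
    smiles: list[str]
    values: np.ndarray          # (n_compounds, 8), NaN where unobserved
    observed: np.ndarray        # (n_compounds, 8) bool
    high_quality_s0: np.ndarray  # (n_compounds,) bool
    task_names: tuple[str, ...] = TASK_NAMES

    def __post_init__(self):
        if self.values.shape != (len(self.compound_ids), len(self.task_names)):
            raise ValueError("values shape mismatch")
        if len(self.task_names) != 8:
            raise ValueError("exactly 8 tasks expected")
        if not np.isfinite(self.values[self.observed]).all():
            raise ValueError("observed values must be finite")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.task_names))
        df.insert(0, "compound_id", self.compound_ids)
        df.insert(1, "smiles", self.smiles)
        for i, t in enumerate(self.task_names):
            df[f"{t}.observed"] = self.observed[:, i].astype(int)
        df["high_quality_s0"] = self.high_quality_s0.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaskTable":
        values = df[list(TASK_NAMES)].to_numpy(float)
        observed = df[[f"{t}.observed" for t in TASK_NAMES]].to_numpy(bool)
        return cls(
            compound_ids=list(df["compound_id"].astype(str)),
            smiles=list(df["smiles"].astype(str)),
            values=values,
            observed=observed,
            high_quality_s0=df["high_quality_s0"].to_numpy(bool),
        )


def build_task_table(
    task_values: dict[str, dict[str, float]],
    smiles_map: dict[str, str],
    high_quality: dict[str, bool] | None = None,
) -> TaskTable:
    """Merge deduplicated per-task value maps into one sparse table.

    ``task_values`` maps task name -> {compound_id -> value}; compounds form
    the outer union over tasks, unobserved cells stay NaN.  A compound id
    missing from ``smiles_map`` is an error, as is an unknown task name.
    """
    for t in task_values:
        if t not in TASK_NAMES:
            raise ValueError(f"unknown task {t!r}; expected one of {TASK_NAMES}")
    ids = sorted({cid for tv in task_values.values() for cid in tv})
    values = np.full((len(ids), len(TASK_NAMES)), np.nan)
    observed = np.zeros((len(ids), len(TASK_NAMES)), bool)
    idx = {cid: i for i, cid in enumerate(ids)}
    for j, t in enumerate(TASK_NAMES):
        for cid, v in task_values.get(t, {}).items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for {cid}/{t}")
            values[idx[cid], j] = v
            observed[idx[cid], j] = True
    hq = np.array([(high_quality or {}).get(cid, False) for cid in ids])
    smiles = []
    for cid in ids:
        if cid not in smiles_map:
            raise ValueError(f"no SMILES for compound {cid}")
        smiles.append(smiles_map[cid])
    return TaskTable(
        compound_ids=ids, smiles=smiles, values=values,
        observed=observed, high_quality_s0=hq,
    )
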