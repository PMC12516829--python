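"""Synthetic assay-data generator.

Emulates the statistical structure of a high-throughput pH 2 / pH 7
solubility screen over a drug-like library: a mixture of neutral, acidic,
basic, ordinary-ampholyte and zwitterionic compounds with up to four pKa's,
true intrinsic solubilities drawn from N(-5, 1.2) log molar, measurement
noise, a 0.1-600 uM dynamic range with censoring, salt forms, amorphous
residual-solid labels, replicate measurements, and a sparse eight-task
target matrix.

SMILES come from a vetted internal list of parseable drug-like scaffolds,
class-tagged by the ionizable groups they carry; pKa lists are drawn per
class and are not derived from the structures (a documented simplification —
the pipeline treats pKa prediction as an input).  Solubility measurements
are simulated with the same relevant-pKa speciation convention the curation
module inverts, so the noise-free pipeline recovers true S0 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curation import (
    Censoring,
    CompoundEntry,
    SolidState,
    SolubilityRecord,
    TASK_NAMES,
)
from .speciation import IonizationModel, relevant_pkas, solubility_at_ph

__all__ = ["GeneratorConfig", "generate_compounds", "simulate_measurements",
           "make_task_values", "simulate_dataset"]

# class-tagged, hand-vetted drug-like scaffolds (all RDKit-parseable)
SCAFFOLDS = {
    "neutral": (
        "CCOC(=O)c1ccccc1", "COc1ccc(C=O)cc1", "CC(C)Cc1ccc(C(C)C)cc1",
        "c1ccc2c(c1)OCO2", "CC(=O)Nc1ccc(OC)cc1", "COc1ccccc1OC",
        "CCN(CC)C(=O)c1ccccc1", "Cc1ccc(S(C)(=O)=O)cc1",
    ),
    "acid": (
        "OC(=O)c1ccccc1", "CC(C)Cc1ccc(cc1)C(C)C(O)=O", "OC(=O)Cc1ccccc1",
        "OC(=O)c1ccccc1O", "Cc1ccccc1C(O)=O", "OC(=O)c1ccc(Cl)cc1",
        "Oc1ccc(cc1)C(F)(F)F", "OC(=O)CCc1ccccc1",
    ),
    "base": (
        "CN1CCN(CC1)c1ccccc1", "NCCc1ccccc1", "CN(C)CCc1ccccc1",
        "c1ccc(CN2CCCC2)cc1", "NCc1ccc(F)cc1", "CCN(CC)CCNC(=O)c1ccccc1",
        "C1CCNCC1", "Cn1ccnc1",
    ),
    "ampholyte": (
        "NCC(=O)Nc1ccccc1C(O)=O", "OC(=O)c1ccc(N2CCNCC2)cc1",
        "NCCc1ccc(O)cc1", "OC(=O)c1ccccc1NCCN",
        "CN1CCN(CC1)c1ccc(cc1)C(O)=O", "NCCCC(O)=O",
    ),
}
SCAFFOLDS["zwitterion"] = SCAFFOLDS["ampholyte"]

# acyclic decoration fragments prepended to scaffolds to diversify structures
FRAGMENTS = ("C", "CC", "CCC", "C(C)C", "CO", "CCO", "C(F)(F)C", "CN(C)C")

CLASSES = ("neutral", "acid", "base", "ampholyte", "zwitterion")

#: assay dynamic range, log10 molar (0.1 uM and 600 uM)
LOG_WINDOW = (math.log10(0.1e-6), math.log10(600e-6))


@dataclass(frozen=True)
class GeneratorConfig:
    n_compounds: int = 500
    seed: int = 0
    class_mix: dict = field(default_factory=lambda: {
        "neutral": 0.20, "acid": 0.30, "base": 0.30,
        "ampholyte": 0.10, "zwitterion": 0.10,
    })
    s0_mean: float = -5.0       # log10 molar
    s0_sd: float = 1.2
    # share of S0 variance explained by molecular size (bigger -> less soluble)
    structure_rho: float = 0.5
    noise_sd: float = 0.3       # log units, per measurement
    duplicate_rate: float = 0.1
    salt_rate: float = 0.05
    amorphous_rate: float = 0.15
    # observation probability of the non-S0 tasks (S0 comes from curation)
    task_sparsity: dict = field(default_factory=lambda: {
        "sol_pH2": 1.0, "sol_pH7": 1.0, "sol_fassif": 0.3,
        "logP": 0.5, "logD_2.6": 0.4, "logD_7.4": 0.4, "logD_10.5": 0.4,
    })

    def __post_init__(self):
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        for k, v in self.class_mix.items():
            if k not in CLASSES or not (0 <= v <= 1):
                raise ValueError(f"bad class_mix entry {k}={v}")
        for name in ("duplicate_rate", "salt_rate", "amorphous_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


def _allocate_classes(config: GeneratorConfig) -> list[str]:
    """Exact largest-remainder class counts, then a seeded shuffle."""
    n = config.n_compounds
    raw = {c: config.class_mix.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return [labels[i] for i in rng.permutation(n)]


def _draw_pkas(cls: str, rng) -> IonizationModel:
    def draw(k):
        return tuple(rng.uniform(2.0, 11.0, size=k))

    if cls == "neutral":
        return IonizationModel()
    if cls == "acid":
        return IonizationModel(acidic_pkas=draw(rng.integers(1, 3)))
    if cls == "base":
        return IonizationModel(basic_pkas=draw(rng.integers(1, 3)))
    # amphoteric classes: enforce the gap constraint by rejection
    want_gap_gt = cls == "ampholyte"
    for _ in range(1000):
        ac, ba = draw(rng.integers(1, 3)), draw(rng.integers(1, 3))
        gap = min(ac) - max(ba)
        if (gap > 2.0) == want_gap_gt:
            return IonizationModel(acidic_pkas=ac, basic_pkas=ba)
    raise RuntimeError("pKa rejection sampling failed")  # pragma: no cover


def _decorated_smiles(cls: str, rng, used: set[str]) -> str:
    """Scaffold with a random acyclic prefix; parseable and cohort-unique."""
    from rdkit import Chem

    for _ in range(200):
        scaffold = SCAFFOLDS[cls][int(rng.integers(len(SCAFFOLDS[cls])))]
        n_frag = int(rng.integers(0, 4))
        prefix = "".join(
            FRAGMENTS[int(rng.integers(len(FRAGMENTS)))] for _ in range(n_frag)
        )
        smiles = prefix + scaffold
        if smiles in used:
            continue
        if Chem.MolFromSmiles(smiles) is not None:
            return smiles
    raise RuntimeError("could not draw a unique parseable SMILES")  # pragma: no cover


def generate_compounds(
    config: GeneratorConfig,
) -> tuple[list[CompoundEntry], dict[str, float], dict[str, str]]:
    """Compounds with class-consistent pKa lists and true S0 values.

    Structures are scaffold + random acyclic decoration, unique within the
    cohort.  True S0 is drawn so that a ``structure_rho`` share of its
    variance tracks molecular size (standardized heavy-atom count over the
    cohort; larger molecules are less soluble) and the rest is independent
    noise, giving a marginal of mean ``s0_mean`` and SD ``s0_sd``.

    Returns (entries, true_s0 by compound_id, class label by compound_id).
    Reproducible for a fixed seed.
    """
    from rdkit import Chem

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    classes = _allocate_classes(config)
    entries, labels = [], {}
    sizes = []
    used: set[str] = set()
    for i, cls in enumerate(classes):
        cid = f"SYN{i:05d}"
        smiles = _decorated_smiles(cls, rng, used)
        used.add(smiles)
        sizes.append(Chem.MolFromSmiles(smiles).GetNumAtoms())
        model = _draw_pkas(cls, rng)
        is_salt = bool(rng.random() < config.salt_rate)
        entries.append(CompoundEntry(
            compound_id=cid, smiles=smiles, ionization=model, is_salt=is_salt,
        ))
        labels[cid] = cls

    sizes = np.asarray(sizes, float)
    sd = sizes.std()
    z = (sizes - sizes.mean()) / sd if sd > 0 else np.zeros_like(sizes)
    rho = config.structure_rho
    eps = rng.standard_normal(len(entries))
    s0 = config.s0_mean + config.s0_sd * (
        -math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
    )
    true_s0 = {e.compound_id: float(v) for e, v in zip(entries, s0)}
    return entries, true_s0, labels


def _speciated(log_s0: float, model: IonizationModel, ph: float) -> float:
    """Solubility at ph under the package's relevant-pKa convention."""
    sub, _ = relevant_pkas(model, ph)
    return solubility_at_ph(log_s0, sub, ph)


def simulate_measurements(
    entries: list[CompoundEntry],
    true_s0: dict[str, float],
    config: GeneratorConfig,
) -> list[SolubilityRecord]:
    """Noisy, censored pH 2 / pH 7 records with replicates and solid labels.

    One record per replicate; every record of a compound-pH pair carries the
    replicate spread (max pairwise difference) of that pair.  Values outside
    the assay window are clipped to the window edge and flagged censored.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lo, hi = LOG_WINDOW
    records = []
    for e in entries:
        amorphous = rng.random() < config.amorphous_rate
        solid = SolidState.amorphous if amorphous else SolidState.crystalline
        for ph in (2.0, 7.0):
            ideal = _speciated(true_s0[e.compound_id], e.ionization, ph)
            n_rep = 2 if rng.random() < config.duplicate_rate else 1
            vals = [ideal + (rng.normal(0.0, config.noise_sd)
                             if config.noise_sd > 0 else 0.0)
                    for _ in range(n_rep)]
            spread = max(vals) - min(vals)
            for v in vals:
                if v < lo:
                    v, cens = lo, Censoring.below_lo
                elif v > hi:
                    v, cens = hi, Censoring.above_hi
                else:
                    cens = Censoring.none
                records.append(SolubilityRecord(
                    compound_id=e.compound_id, ph=ph, log_s=v,
                    solid_state=solid, censored=cens,
                    replicate_spread=spread,
                ))
    return records


def make_task_values(
    entries: list[CompoundEntry],
    true_s0: dict[str, float],
    config: GeneratorConfig,
) -> dict[str, dict[str, float]]:
    """Planted auxiliary-task targets with exact-count sparsity.

    Solubility tasks follow the speciation curve (FaSSIF gets a solubilizing
    boost); logP / logD are noisy linear functions of S0 and molecule size —
    enough correlation structure to exercise multi-task learning, with no
    claim of partitioning physics.  For each task, exactly
    round(p * n_compounds) compounds are observed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n = len(entries)
    sizes = {e.compound_id: float(len(e.smiles)) for e in entries}
    out: dict[str, dict[str, float]] = {}
    for task in TASK_NAMES:
        if task == "S0":
            continue
        p = config.task_sparsity.get(task, 0.0)
        k = int(round(p * n))
        chosen = rng.permutation(n)[:k]
        vals = {}
        for i in chosen:
            e = entries[i]
            s0 = true_s0[e.compound_id]
            noise = rng.normal(0.0, 0.2)
            if task == "sol_pH2":
                vals[e.compound_id] = _speciated(s0, e.ionization, 2.0) + noise
            elif task == "sol_pH7":
                vals[e.compound_id] = _speciated(s0, e.ionization, 7.0) + noise
            elif task == "sol_fassif":
                vals[e.compound_id] = s0 + 0.8 + noise
            elif task == "logP":
                vals[e.compound_id] = -0.8 * s0 + 0.02 * sizes[e.compound_id] + noise
            else:  # logD at 2.6 / 7.4 / 10.5
                shift = {"logD_2.6": 1.0, "logD_7.4": 0.3, "logD_10.5": 0.8}[task]
                vals[e.compound_id] = (-0.8 * s0 + 0.02 * sizes[e.compound_id]
                                       - shift + noise)
        out[task] = vals
    return out


def simulate_dataset(config: GeneratorConfig):
    """Convenience wrapper: compounds, true S0, records, auxiliary targets."""
    entries, true_s0, labels = generate_compounds(config)
    records = simulate_measurements(entries, true_s0, config)
    tasks = make_task_values(entries, true_s0, config)
    return entries, true_s0, labels, records, tasks
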