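"""Henderson–Hasselbalch pH–solubility speciation.

For an ionizable compound the total equilibrium solubility factorizes as
``S(pH) = S0 * Phi(pH)`` where ``S0`` is the intrinsic solubility of the
neutral species and ``Phi >= 1`` is the ionization factor.  With the relevant
acidic pKa's ``a_1 <= a_2 <= ...`` and basic pKa's ``b_1 >= b_2 >= ...`` the
cumulative speciation expansion is

    Phi(pH) = 1 + sum_k 10^(k*pH - (a_1+...+a_k))
                + sum_k 10^((b_1+...+b_k) - k*pH)

which reproduces the standard monoprotic/diprotic/triprotic acid and base
cases as well as the ordinary-ampholyte case.  Cross-terms for simultaneously
zwitterionic microspecies are not modelled (zwitterions are discarded during
curation).

All solubilities are log10 molar; pH and pKa are in pH units.  Evaluation is
done in log space (log-sum-exp) so that |pH - pKa| gaps of 20 or more do not
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IonizationModel",
    "SpeciationResult",
    "TooManyIonizableGroups",
    "ionization_factor",
    "solubility_at_ph",
    "intrinsic_from_measured",
    "relevant_pkas",
    "ionized_fraction",
]

#: Combined relevant-pKa budget: more groups than this make the speciation
#: expansion too error-amplifying to invert reliably.
MAX_RELEVANT_PKAS = 3

#: Default ionized-fraction threshold below which a group is irrelevant.
DEFAULT_FRACTION_THRESHOLD = 0.01

_LN10 = math.log(10.0)


class TooManyIonizableGroups(ValueError):
    """Raised when more than MAX_RELEVANT_PKAS pKa's would enter Phi.

    Carries ``n_relevant`` so callers (curation, profiler) can decide to
    discard the compound or mark the pH point undetermined.
    """

    def __init__(self, n_relevant: int):
        self.n_relevant = n_relevant
        super().__init__(
            f"{n_relevant} relevant pKa's exceed the maximum of {MAX_RELEVANT_PKAS}"
        )


@dataclass(frozen=True)
class IonizationModel:
    """Ordered pKa lists of one compound.

    ``acidic_pkas`` sorted ascending (the smallest deprotonates first above
    its pKa); ``basic_pkas`` sorted descending (the largest protonates first
    below its pKa).  Lists are normalized to these orders on construction.
    """

    acidic_pkas: tuple[float, ...] = field(default=())
    basic_pkas: tuple[float, ...] = field(default=())

    def __post_init__(self):
        ac = tuple(sorted(float(p) for p in self.acidic_pkas))
        ba = tuple(sorted((float(p) for p in self.basic_pkas), reverse=True))
        for p in ac + ba:
            if not math.isfinite(p):
                raise ValueError(f"non-finite pKa: {p}")
        object.__setattr__(self, "acidic_pkas", ac)
        object.__setattr__(self, "basic_pkas", ba)

    @property
    def n_pkas(self) -> int:
        return len(self.acidic_pkas) + len(self.basic_pkas)

    @property
    def kind(self) -> str:
        """One of 'neutral', 'acid', 'base', 'amphoteric'."""
        if self.acidic_pkas and self.basic_pkas:
            return "amphoteric"
        if self.acidic_pkas:
            return "acid"
        if self.basic_pkas:
            return "base"
        return "neutral"


@dataclass(frozen=True)
class SpeciationResult:
    """log10 of the ionization factor and how many pKa's produced it."""

    log_phi: float
    n_relevant: int


def _check_ph(ph: float) -> float:
    ph = float(ph)
    if not math.isfinite(ph):
        raise ValueError(f"pH must be finite, got {ph}")
    return ph


def ionization_factor(model: IonizationModel, ph: float) -> SpeciationResult:
    """log10 Phi(pH) for ``model`` via the cumulative speciation expansion.

    Raises :class:`TooManyIonizableGroups` when the model carries more than
    MAX_RELEVANT_PKAS pKa's; filter with :func:`relevant_pkas` first.
    """
    ph = _check_ph(ph)
    n = model.n_pkas
    if n > MAX_RELEVANT_PKAS:
        raise TooManyIonizableGroups(n)
    # exponents of the base-10 terms, including the neutral species' 0
    exps = [0.0]
    acc = 0.0
    for k, a in enumerate(model.acidic_pkas, start=1):
        acc += a
        exps.append(k * ph - acc)
    acc = 0.0
    for k, b in enumerate(model.basic_pkas, start=1):
        acc += b
        exps.append(acc - k * ph)
    # log10-sum-exp anchored at the largest exponent
    m = max(exps)
    s = sum(math.exp((e - m) * _LN10) for e in exps)
    log_phi = m + math.log10(s)
    # the expansion always contains the 10^0 neutral term, so Phi >= 1
    log_phi = max(log_phi, 0.0)
    return SpeciationResult(log_phi=log_phi, n_relevant=n)


def solubility_at_ph(log_s0: float, model: IonizationModel, ph: float) -> float:
    """log10 S(pH) = log10 S0 + log10 Phi(pH); never below log_s0."""
    log_s0 = float(log_s0)
    if not math.isfinite(log_s0):
        raise ValueError(f"log_s0 must be finite, got {log_s0}")
    return log_s0 + ionization_factor(model, ph).log_phi


def intrinsic_from_measured(
    log_s_measured: float, model: IonizationModel, ph: float
) -> float:
    """Invert the speciation map: log10 S0 = log10 S(pH) - log10 Phi(pH)."""
    log_s_measured = float(log_s_measured)
    if not math.isfinite(log_s_measured):
        raise ValueError(f"log_s_measured must be finite, got {log_s_measured}")
    return log_s_measured - ionization_factor(model, ph).log_phi


def ionized_fraction(pka: float, ph: float, acidic: bool) -> float:
    """Fraction of the group ionized at ``ph``.

    Acidic groups ionize above their pKa: f = 1/(1+10^(pKa-pH)).
    Basic groups ionize below: f = 1/(1+10^(pH-pKa)).
    """
    d = (pka - ph) if acidic else (ph - pka)
    if d > 300:  # 10**d would overflow float64
        return 0.0
    return 1.0 / (1.0 + 10.0 ** d)


def relevant_pkas(
    model: IonizationModel,
    ph: float,
    ionized_fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
) -> tuple[IonizationModel, int]:
    """Keep pKa's whose group is appreciably ionized at ``ph``.

    A group is relevant when its ionized fraction at ``ph`` is >= the
    threshold (boundary inclusive).  If more than MAX_RELEVANT_PKAS survive,
    the ones with the largest fractions are kept; the returned ``n_relevant``
    is the pre-cap count so callers can detect the >3 situation.

    Returns (filtered model, n_relevant).
    """
    ph = _check_ph(ph)
    if not (0.0 < ionized_fraction_threshold < 0.5):
        raise ValueError("ionized_fraction_threshold must be in (0, 0.5)")
    cands: list[tuple[float, float, bool]] = []  # (fraction, pka, acidic)
    for a in model.acidic_pkas:
        f = ionized_fraction(a, ph, acidic=True)
        if f >= ionized_fraction_threshold:
            cands.append((f, a, True))
    for b in model.basic_pkas:
        f = ionized_fraction(b, ph, acidic=False)
        if f >= ionized_fraction_threshold:
            cands.append((f, b, False))
    n_relevant = len(cands)
    if n_relevant > MAX_RELEVANT_PKAS:
        cands.sort(key=lambda t: -t[0])
        cands = cands[:MAX_RELEVANT_PKAS]
    kept_ac = tuple(p for _, p, ac in cands if ac)
    kept_ba = tuple(p for _, p, ac in cands if not ac)
    return IonizationModel(acidic_pkas=kept_ac, basic_pkas=kept_ba), n_relevant


def naive_ionization_factor(model: IonizationModel, ph: float) -> float:
    """Direct (overflow-prone) evaluation of log10 Phi; test oracle only."""
    total = 1.0
    acc = 0.0
    for k, a in enumerate(model.acidic_pkas, start=1):
        acc += a
        total += 10.0 ** (k * ph - acc)
    acc = 0.0
    for k, b in enumerate(model.basic_pkas, start=1):
        acc += b
        total += 10.0 ** (acc - k * ph)
    return np.log10(total)
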