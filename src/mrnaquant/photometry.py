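"""Construct-level photometric quantities.

The molar absorption coefficient of a hydrolyzed RNA at 260 nm is additive
over its residues:

    MAC260 = sum_i n_i * eps_260(i) + cap contribution

so it is exactly linear in every residue count, and therefore in any
substitution fraction.  Hypochromicity of a modified construct is expressed
as the ratio of its MAC260 to that of the unmodified isosequence; applying
the unmodified coefficient to a modified sample under-estimates its
concentration by ``100 * (1 - ratio)`` percent.

Molecular weights are average masses under the free-acid convention:

    MW = sum_i n_i * residue_mass(i) + H2O + 5'-end adjustment

where the 5' end is a monophosphate (+0), hydroxyl (-HPO3), triphosphate
(+2 HPO3 — what uncapped T7 transcription yields, the default), or a cap
(hydroxyl baseline plus the cap's mass contribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import UndefinedRatioError, ValidationError
from .registry import Registry
from .sequence_io import Composition, ModificationScheme, apply_scheme, composition

__all__ = [
    "MacResult",
    "mac260",
    "molecular_weight",
    "compute_mac",
    "hypochromicity_ratio",
    "underestimation_percent",
    "legacy_mass_concentration",
    "WATER_MASS",
    "HPO3_MASS",
    "LEGACY_SSRNA_FACTOR",
]

WATER_MASS = 18.015  # g/mol, average
HPO3_MASS = 79.980  # g/mol, average (metaphosphate unit)
#: Conventional single-stranded RNA estimate, ug/mL per absorbance unit.
LEGACY_SSRNA_FACTOR = 40.0

FivePrime = Literal["triphosphate", "monophosphate", "hydroxyl"]


@dataclass(frozen=True)
class MacResult:
    """Molar absorption, molecular weight, and mass-extinction of a construct.

    ``mass_extinction`` is the mass concentration (ug/mL) producing one
    absorbance unit at 1 cm path: ``1000 * mol_weight / mac_260``.
    """

    mac_260: float
    mol_weight: float
    composition: Composition

    @property
    def mass_extinction(self) -> float:
        if self.mac_260 == 0:
            raise UndefinedRatioError("mass extinction undefined for zero MAC260")
        return 1000.0 * self.mol_weight / self.mac_260


def mac260(comp: Composition, reg: Registry) -> float:
    """Molar absorption coefficient at 260 nm, M^-1 cm^-1, cap included."""
    total = sum(n * reg.nucleoside(code).eps_260 for code, n in comp.counts.items())
    return total + reg.cap(comp.cap).eps_260_add


def molecular_weight(
    comp: Composition,
    reg: Registry,
    five_prime: FivePrime = "triphosphate",
) -> float:
    """Average molecular weight in g/mol; 0 for an empty composition.

    A capped construct takes the cap's mass contribution on a 5'-hydroxyl
    baseline and ignores ``five_prime``.
    """
    if comp.length == 0:
        return 0.0
    mass = sum(n * reg.nucleoside(code).residue_mass for code, n in comp.counts.items())
    mass += WATER_MASS  # one terminal water; baseline is the 5'-monophosphate form
    if comp.cap != "none":
        return mass - HPO3_MASS + reg.cap(comp.cap).mass_add
    if five_prime == "monophosphate":
        return mass
    if five_prime == "hydroxyl":
        return mass - HPO3_MASS
    if five_prime == "triphosphate":
        return mass + 2.0 * HPO3_MASS
    raise ValidationError(f"unknown 5' end {five_prime!r}")


def compute_mac(
    comp: Composition,
    reg: Registry,
    five_prime: FivePrime = "triphosphate",
) -> MacResult:
    return MacResult(
        mac_260=mac260(comp, reg),
        mol_weight=molecular_weight(comp, reg, five_prime),
        composition=comp,
    )


def _modified_pair(
    seq: str,
    scheme: ModificationScheme,
    cap: str,
    reg: Registry,
) -> tuple[float, float]:
    base = composition(seq, cap=cap)
    mod = apply_scheme(base, scheme)
    return mac260(mod, reg), mac260(base, reg)


def hypochromicity_ratio(
    seq: str,
    scheme: ModificationScheme,
    cap: str,
    reg: Registry,
) -> float:
    """MAC260(modified) / MAC260(unmodified), caps identical on both sides.

    The ratio is <= 1 whenever every substitution in the scheme is
    hypochromic at 260 nm; an empty scheme gives exactly 1.
    """
    mod, ref = _modified_pair(seq, scheme, cap, reg)
    if ref == 0:
        raise UndefinedRatioError(
            "hypochromicity ratio undefined: unmodified MAC260 is zero (empty sequence?)"
        )
    return mod / ref


def underestimation_percent(
    seq: str,
    scheme: ModificationScheme,
    cap: str,
    reg: Registry,
) -> float:
    """Percent by which concentration is under-estimated when the unmodified
    coefficient is applied to the modified construct."""
    return 100.0 * (1.0 - hypochromicity_ratio(seq, scheme, cap, reg))


def legacy_mass_concentration(a260: float, dilution: float = 1.0) -> float:
    """Stock mass concentration in ug/mL from the conventional ssRNA factor
    of 40 ug/mL per absorbance unit. Provided for side-by-side comparison."""
    if a260 < 0:
        raise ValidationError(f"absorbance must be non-negative, got {a260}")
    if dilution < 1:
        raise ValidationError(f"dilution factor must be >= 1, got {dilution}")
    return LEGACY_SSRNA_FACTOR * a260 * dilution
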