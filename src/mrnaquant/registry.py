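"""Photometric and mass constants for standard, modified, and cap nucleosides.

The registry is the single source of the per-nucleoside absorption peak
wavelength (``lambda_max``, nm), the molar absorption coefficient at that
peak (``eps_max``, M^-1 cm^-1), the molar absorption coefficient at 260 nm
(``eps_260``, M^-1 cm^-1), and the average mass of the internal
monophosphate residue (g/mol).  A builtin table covering A, C, G, U, T,
pseudouridine (Y), N1-methylpseudouridine (m1Y), 5-methylcytidine (m5C), and
7-methylguanosine (m7G) ships with the package; users may override any field
of any entry, or add entries, through a YAML config file with the same
schema as the builtin file (``data/nucleosides.yaml``).

Values are for dilute aqueous buffer at neutral pH and carry no
temperature, pH, or ionic-strength dependence.  They are nucleoside
measurements applied to hydrolyzed (mononucleotide) samples; the residual
difference between nucleoside and mononucleotide molar absorption is below
the accuracy the calculator targets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import IO, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigError, UnknownCodeError

__all__ = [
    "NucleosideSpec",
    "CapSpec",
    "Registry",
    "load_registry",
    "delta_epsilon_percent",
    "delta_lambda_max",
    "normalize_code",
]

#: Unicode / display spellings accepted on input for ASCII registry codes.
CODE_ALIASES = {
    "Ψ": "Y",
    "ψ": "Y",
    "m1Ψ": "m1Y",
    "m¹Ψ": "m1Y",
    "m1ψ": "m1Y",
    "m⁵C": "m5C",
    "m5c": "m5C",
    "m⁷G": "m7G",
    "m7g": "m7G",
}


def normalize_code(code: str) -> str:
    """Map Unicode or case-variant spellings of a residue code to its ASCII form."""
    code = code.strip()
    return CODE_ALIASES.get(code, code)


class NucleosideSpec(BaseModel):
    """Photometric and mass constants for one residue."""

    model_config = ConfigDict(frozen=True)

    code: str
    name: str
    lambda_max: float
    eps_max: float
    eps_260: float
    residue_mass: float
    provenance: str = ""

    @field_validator("eps_max", "eps_260", "residue_mass")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("lambda_max")
    @classmethod
    def _in_uv_window(cls, v: float) -> float:
        if not 200.0 <= v <= 300.0:
            raise ValueError(f"lambda_max must lie in [200, 300] nm, got {v}")
        return v

    @model_validator(mode="after")
    def _eps260_below_peak(self) -> "NucleosideSpec":
        if self.eps_260 > self.eps_max:
            raise ValueError(
                f"{self.code}: eps_260 ({self.eps_260}) exceeds eps_max ({self.eps_max})"
            )
        return self


class CapSpec(BaseModel):
    """Absorption and mass contribution of a 5' cap moiety.

    ``eps_260_add`` is the extra molar absorption at 260 nm contributed by
    the 7-methylguanosine chromophore; ``mass_add`` is the extra average
    mass of the cap moiety including the 5'-5' triphosphate bridge, taken
    relative to a 5'-hydroxyl end.  ``none`` contributes nothing — the
    5'-end chemistry of an uncapped construct is handled by the molecular
    weight calculation.
    """

    model_config = ConfigDict(frozen=True)

    code: Literal["none", "cap0", "cap1"]
    eps_260_add: float
    mass_add: float

    @model_validator(mode="after")
    def _none_is_empty(self) -> "CapSpec":
        if self.code == "none" and (self.eps_260_add != 0.0 or self.mass_add != 0.0):
            raise ValueError("cap 'none' must contribute zero absorption and mass")
        if self.eps_260_add < 0 or self.mass_add < 0:
            raise ValueError(f"cap {self.code}: contributions must be non-negative")
        return self


REQUIRED_CODES = ("A", "C", "G", "U", "T", "Y", "m1Y", "m5C")
REQUIRED_CAPS = ("none", "cap0", "cap1")


class Registry(BaseModel):
    """Validated table of nucleoside and cap constants."""

    model_config = ConfigDict(frozen=True)

    entries: dict[str, NucleosideSpec]
    caps: dict[str, CapSpec]
    source: str = "builtin"

    @model_validator(mode="after")
    def _complete(self) -> "Registry":
        missing = [c for c in REQUIRED_CODES if c not in self.entries]
        if missing:
            raise ValueError(f"registry is missing required nucleosides: {missing}")
        missing_caps = [c for c in REQUIRED_CAPS if c not in self.caps]
        if missing_caps:
            raise ValueError(f"registry is missing required caps: {missing_caps}")
        return self

    def nucleoside(self, code: str) -> NucleosideSpec:
        code = normalize_code(code)
        try:
            return self.entries[code]
        except KeyError:
            raise UnknownCodeError(code) from None

    def cap(self, code: str) -> CapSpec:
        code = normalize_code(code)
        try:
            return self.caps[code]
        except KeyError:
            raise UnknownCodeError(code) from None

    def __contains__(self, code: object) -> bool:
        return isinstance(code, str) and normalize_code(code) in self.entries

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        """Serialize to the config dialect; reloading yields identical entries."""
        doc = {
            "nucleosides": {
                code: {
                    k: v
                    for k, v in spec.model_dump().items()
                    if k != "code" and not (k == "provenance" and v == "")
                }
                for code, spec in self.entries.items()
            },
            "caps": {
                code: {k: v for k, v in spec.model_dump().items() if k != "code"}
                for code, spec in self.caps.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_yaml())


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate codes)."""


def _no_duplicates(loader: _StrictLoader, node: yaml.MappingNode, deep: bool = False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in seen:
            raise ConfigError(
                f"duplicate code {key!r} at line {key_node.start_mark.line + 1}"
            )
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep=deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def _parse_config(text: str, source: str) -> dict:
    try:
        doc = yaml.load(text, Loader=_StrictLoader)
    except ConfigError:
        raise
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed registry config {source}{where}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"registry config {source} must be a mapping of sections")
    unknown = set(doc) - {"nucleosides", "caps"}
    if unknown:
        raise ConfigError(f"registry config {source}: unknown sections {sorted(unknown)}")
    return doc


def _builtin_text() -> str:
    return resources.files("mrnaquant.data").joinpath("nucleosides.yaml").read_text()


def load_registry(
    config_path: Optional[Union[str, Path, IO[str]]] = None,
) -> Registry:
    """Load the builtin constants table, optionally overridden by a config file.

    User entries override builtins per code and per field: a config block
    that specifies only ``eps_260`` for ``U`` changes that one field and
    keeps every other builtin value.  New codes must specify all fields.

    Raises
    ------
    ConfigError
        If the file cannot be parsed (the message names the line) or an
        entry violates an invariant (the message names the code).
    """
    builtin = _parse_config(_builtin_text(), "builtin")
    merged_nuc: dict[str, dict] = {c: dict(v) for c, v in builtin["nucleosides"].items()}
    merged_caps: dict[str, dict] = {c: dict(v) for c, v in builtin["caps"].items()}
    source = "builtin"

    if config_path is not None:
        if hasattr(config_path, "read"):
            text = config_path.read()
            source = getattr(config_path, "name", "<stream>")
        else:
            path = Path(config_path)
            if not path.exists():
                raise FileNotFoundError(f"registry config not found: {path}")
            text = path.read_text()
            source = str(path)
        user = _parse_config(text, source)
        for code, fields in (user.get("nucleosides") or {}).items():
            code = normalize_code(str(code))
            if not isinstance(fields, dict):
                raise ConfigError(f"{source}: entry {code!r} must be a mapping of fields")
            merged_nuc.setdefault(code, {}).update(fields)
        for code, fields in (user.get("caps") or {}).items():
            code = normalize_code(str(code))
            if not isinstance(fields, dict):
                raise ConfigError(f"{source}: cap {code!r} must be a mapping of fields")
            merged_caps.setdefault(code, {}).update(fields)

    entries: dict[str, NucleosideSpec] = {}
    for code, fields in merged_nuc.items():
        try:
            entries[code] = NucleosideSpec(code=code, **fields)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid registry entry {code!r}: {exc}") from exc
    caps: dict[str, CapSpec] = {}
    for code, fields in merged_caps.items():
        try:
            caps[code] = CapSpec(code=code, **fields)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid cap entry {code!r}: {exc}") from exc

    try:
        return Registry(entries=entries, caps=caps, source=source)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def delta_epsilon_percent(
    reg: Registry,
    ref_code: str,
    mod_code: str,
    wavelength_mode: Literal["at260", "at_max"] = "at260",
) -> float:
    """Signed percent change in molar absorption from ``ref_code`` to ``mod_code``.

    ``at260`` compares eps_260; ``at_max`` compares each nucleoside's own
    peak coefficient.  Negative values mean the modified nucleoside is
    hypochromic relative to the reference.
    """
    if wavelength_mode not in ("at260", "at_max"):
        raise ValueError(f"wavelength_mode must be 'at260' or 'at_max', got {wavelength_mode!r}")
    attr = "eps_260" if wavelength_mode == "at260" else "eps_max"
    ref = getattr(reg.nucleoside(ref_code), attr)
    mod = getattr(reg.nucleoside(mod_code), attr)
    return 100.0 * (mod - ref) / ref


def delta_lambda_max(reg: Registry, ref_code: str, mod_code: str) -> float:
    """Shift of the absorption peak in nm (positive = bathochromic)."""
    return reg.nucleoside(mod_code).lambda_max - reg.nucleoside(ref_code).lambda_max
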