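"""Organ-specific acquisition presets, protocol compliance checks and the
reporting checklist.

The consensus recommendations organise b-value sampling into nested tiers:
an *abbreviated* 3-value set (b = 0, the segmented-fit threshold, and an
organ-specific upper limit) sufficient for D and f; a *minimal* 6-value set
(abbreviated plus three design-optimised values) sufficient for all of
(D, f, D*); and an *advanced* tier that may add values but must contain the
minimal set.  Presets also carry acquisition minima (TR, averages,
directions), fat-suppression expectations and literature parameter priors
used by the design and planning modules.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "OrganPreset",
    "AcquisitionProtocol",
    "ComplianceFinding",
    "ORGANS",
    "get_preset",
    "protocol_from_preset",
    "check_protocol",
    "reporting_checklist",
]

ORGANS = ("brain", "breast", "kidney", "liver", "muscle", "pancreas")
TIERS = ("abbreviated", "minimal", "advanced")


@dataclass(frozen=True)
class OrganPreset:
    """Per-organ consensus constants (b-value tiers, acquisition minima,
    literature parameter priors)."""

    organ: str
    abbreviated_b: tuple[float, ...]
    minimal_b: tuple[float, ...]
    b_threshold: float
    tr_min: float
    te_rule: str
    averages_min: int
    n_directions_min: int
    fat_suppression: str
    in_plane_resolution_mm: tuple[float, float]
    slice_thickness_mm: tuple[float, float]
    prior: dict[str, dict[str, float]]
    reference_snr: float = 25.0

    def __post_init__(self) -> None:
        abbrev, minimal = Counter(self.abbreviated_b), Counter(self.minimal_b)
        if len(self.abbreviated_b) != 3 or 0 not in self.abbreviated_b:
            raise ValueError(f"{self.organ}: abbreviated tier must be 3 b-values incl. 0")
        if len(self.minimal_b) != 6:
            raise ValueError(f"{self.organ}: minimal tier must have 6 b-values")
        if abbrev - minimal:
            raise ValueError(f"{self.organ}: abbreviated_b must be a sub-multiset of minimal_b")
        if self.b_threshold not in self.minimal_b:
            raise ValueError(f"{self.organ}: b_threshold must be in the minimal tier")
        if any(b % 10 for b in self.minimal_b):
            raise ValueError(f"{self.organ}: preset b-values must be multiples of 10")

    def bvalues(self, tier: str = "minimal") -> tuple[float, ...]:
        if tier == "abbreviated":
            return self.abbreviated_b
        if tier in ("minimal", "advanced"):
            return self.minimal_b
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")

    def prior_means(self) -> dict[str, float]:
        return {k: v["mean"] for k, v in self.prior.items()}


def _default_constants() -> dict:
    with resources.files("ivimkit.data").joinpath("organ_presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def get_preset(organ: str, constants_file: str | Path | None = None) -> OrganPreset:
    """Load the preset for ``organ``, optionally from a user constants file
    (YAML, same schema as the packaged ``organ_presets.yaml``)."""
    if constants_file is None:
        constants = _default_constants()
    else:
        with open(constants_file) as fh:
            constants = yaml.safe_load(fh)
    table = constants["organs"]
    if organ not in table:
        raise KeyError(
            f"unknown organ {organ!r}; supported organs: {sorted(table)}"
        )
    entry = dict(table[organ])
    return OrganPreset(
        organ=organ,
        abbreviated_b=tuple(entry["abbreviated_b"]),
        minimal_b=tuple(entry["minimal_b"]),
        b_threshold=float(entry["b_threshold"]),
        tr_min=float(entry["tr_min"]),
        te_rule=str(entry["te_rule"]),
        averages_min=int(entry["averages_min"]),
        n_directions_min=int(entry["n_directions_min"]),
        fat_suppression=str(entry["fat_suppression"]),
        in_plane_resolution_mm=tuple(entry["in_plane_resolution_mm"]),
        slice_thickness_mm=tuple(entry["slice_thickness_mm"]),
        prior={k: dict(v) for k, v in entry["prior"].items()},
        reference_snr=float(constants.get("reference_snr", 25)),
    )


@dataclass
class AcquisitionProtocol:
    """A user acquisition protocol to validate and report.

    Only ``organ`` and ``bvalues`` are required; every other field is optional
    and simply marked missing by the reporting checklist when absent.  Times:
    tr in s, te / delta_big / delta_small / echo_spacing in ms.
    """

    organ: str
    bvalues: list[float] = field(default_factory=list)
    n_directions: int | None = None
    n_averages: int | None = None
    tr: float | None = None
    te: float | None = None
    delta_big: float | None = None
    delta_small: float | None = None
    max_gradient: float | None = None
    slew_rate: float | None = None
    field_strength: float | None = None
    fat_suppression: str | None = None
    voxel_size_mm: list[float] | None = None
    slice_thickness_mm: float | None = None
    echo_train_length: int | None = None
    echo_spacing: float | None = None
    bandwidth: float | None = None
    acceleration_factor: float | None = None
    oversampling: str | None = None
    slice_gap_mm: float | None = None
    slice_order: str | None = None
    reconstruction: str | None = None
    preprocessing: list[str] | None = None

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.bvalues):
            raise ValueError("b-values must be >= 0")
        for name in ("tr", "te"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when provided")
        for name in ("n_directions", "n_averages"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1 when provided")

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionProtocol":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def protocol_from_preset(preset: OrganPreset, tier: str = "minimal") -> AcquisitionProtocol:
    """A reference protocol realising the preset's own recommendations."""
    mid = lambda pair: 0.5 * (pair[0] + pair[1])  # noqa: E731
    return AcquisitionProtocol(
        organ=preset.organ,
        bvalues=list(preset.bvalues(tier)),
        n_directions=preset.n_directions_min,
        n_averages=preset.averages_min,
        tr=preset.tr_min,
        te=60.0,
        fat_suppression=preset.fat_suppression,
        voxel_size_mm=[mid(preset.in_plane_resolution_mm)] * 2
        + [mid(preset.slice_thickness_mm)],
        slice_thickness_mm=mid(preset.slice_thickness_mm),
    )


@dataclass(frozen=True)
class ComplianceFinding:
    severity: str  # pass | warn | fail
    field_name: str
    observed: object
    recommended: object
    citation: str  # resolvable preset field name

    def __str__(self) -> str:
        return (
            f"[{self.severity.upper():>4}] {self.field_name}: observed "
            f"{self.observed!r}, recommended {self.recommended!r} ({self.citation})"
        )


def _tier_finding(protocol, preset, tier) -> ComplianceFinding:
    have = Counter(float(b) for b in protocol.bvalues)
    if tier == "abbreviated":
        need = Counter(float(b) for b in preset.abbreviated_b)
    else:  # minimal and advanced both require containment of the minimal set
        need = Counter(float(b) for b in preset.minimal_b)
    missing = need - have
    sev = "pass" if not missing else "fail"
    obs = sorted(have.elements())
    rec = f"must contain {sorted(need.elements())} (multiset)"
    if missing:
        rec += f"; missing {sorted(missing.elements())}"
    return ComplianceFinding(sev, "bvalues", obs, rec, "minimal_b" if tier != "abbreviated" else "abbreviated_b")


def check_protocol(
    protocol: AcquisitionProtocol, preset: OrganPreset, tier: str = "minimal"
) -> list[ComplianceFinding]:
    """Validate a protocol against an organ preset at the given tier.

    Tier containment is checked as multisets (advanced ⊇ minimal ⊇
    abbreviated, so repeated b = 0 entries count).  Never raises on
    non-compliance — one finding per checked field; raises only on an
    organ mismatch or unknown tier.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    if protocol.organ != preset.organ:
        raise ValueError(
            f"protocol organ {protocol.organ!r} does not match preset {preset.organ!r}"
        )
    findings = [_tier_finding(protocol, preset, tier)]

    def check(name, observed, ok, recommended, citation, severity="fail"):
        if observed is None:
            findings.append(ComplianceFinding("warn", name, None, recommended, citation))
        else:
            findings.append(
                ComplianceFinding("pass" if ok else severity, name, observed, recommended, citation)
            )

    p = protocol
    check("tr", p.tr, p.tr is not None and p.tr >= preset.tr_min,
          f">= {preset.tr_min} s", "tr_min")
    check("n_averages", p.n_averages,
          p.n_averages is not None and p.n_averages >= preset.averages_min,
          f">= {preset.averages_min}", "averages_min")
    check("n_directions", p.n_directions,
          p.n_directions is not None and p.n_directions >= preset.n_directions_min,
          f">= {preset.n_directions_min}", "n_directions_min")
    if p.voxel_size_mm is not None:
        lo, hi = preset.in_plane_resolution_mm
        inplane = max(p.voxel_size_mm[:2])
        check("in_plane_resolution_mm", inplane, lo <= inplane <= hi,
              f"[{lo}, {hi}] mm", "in_plane_resolution_mm")
    else:
        check("in_plane_resolution_mm", None, False,
              list(preset.in_plane_resolution_mm), "in_plane_resolution_mm")
    lo, hi = preset.slice_thickness_mm
    check("slice_thickness_mm", p.slice_thickness_mm,
          p.slice_thickness_mm is not None and lo <= p.slice_thickness_mm <= hi,
          f"[{lo}, {hi}] mm", "slice_thickness_mm")
    # fat suppression cannot affect fitting -> warn only
    check("fat_suppression", p.fat_suppression,
          p.fat_suppression == preset.fat_suppression,
          preset.fat_suppression, "fat_suppression", severity="warn")
    return findings


#: Reporting items recommended for reproducible IVIM studies: acquisition
#: timing, sequence details, reconstruction and fitting metadata.
CHECKLIST_ITEMS: tuple[tuple[str, str], ...] = (
    ("tr", "repetition time TR (s)"),
    ("te", "echo time TE (ms)"),
    ("delta_big", "diffusion gradient separation Δ (ms)"),
    ("delta_small", "diffusion gradient duration δ (ms)"),
    ("max_gradient", "maximum gradient strength (mT/m)"),
    ("slew_rate", "maximum slew rate (T/m/s)"),
    ("fat_suppression", "fat suppression type"),
    ("voxel_size_mm", "acquired voxel size (mm)"),
    ("echo_train_length", "echo train length"),
    ("echo_spacing", "echo spacing (ms)"),
    ("bandwidth", "receiver bandwidth (Hz/px)"),
    ("acceleration_factor", "parallel-imaging acceleration factor"),
    ("oversampling", "oversampling factors and directions"),
    ("slice_gap_mm", "slice gap (mm)"),
    ("slice_order", "slice acquisition order"),
    ("reconstruction", "reconstruction settings (interpolation, zero filling, filtering)"),
    ("preprocessing", "individual pre-processing steps"),
    ("fit_algorithm", "fit algorithm"),
    ("fit_initial_guess", "fit initial guess"),
    ("fit_constraints", "fit constraints"),
)


def reporting_checklist(
    protocol: AcquisitionProtocol, fit_metadata: dict | None = None
) -> dict:
    """Build the study-reporting checklist.

    Returns a machine-readable dict with one entry per recommended reporting
    item, each marked provided/missing, plus a Markdown rendering under the
    ``"markdown"`` key.  ``fit_metadata`` supplies the fitting entries
    (``fit_algorithm``, ``fit_initial_guess``, ``fit_constraints``).
    """
    fit_metadata = fit_metadata or {}
    entries = []
    for key, label in CHECKLIST_ITEMS:
        if key.startswith("fit_"):
            value = fit_metadata.get(key)
        else:
            value = getattr(protocol, key, None)
        entries.append(
            {"item": key, "label": label, "provided": value is not None, "value": value}
        )
    n_missing = sum(not e["provided"] for e in entries)
    lines = ["# IVIM reporting checklist", ""]
    for e in entries:
        mark = "x" if e["provided"] else " "
        val = "" if e["value"] is None else f" — {e['value']}"
        lines.append(f"- [{mark}] {e['label']}{val}")
    lines.append("")
    lines.append(f"{len(entries) - n_missing}/{len(entries)} items provided.")
    return {
        "organ": protocol.organ,
        "entries": entries,
        "n_items": len(entries),
        "n_missing": n_missing,
        "markdown": "\n".join(lines),
    }
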