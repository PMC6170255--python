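"""Synthetic inhibition matrices built from motivating compound archetypes.

Three archetypes span the off-target behaviours a selectivity score must
discriminate:

* ``clean_selective`` — strong on-target inhibition, near-zero everywhere
  else (the compound one hopes to find);
* ``pan_weak`` — same on-target inhibition but every off-target weakly hit
  (default 10%), the promiscuous-but-shallow case;
* ``few_strong`` — a handful (2-10) of off-targets inhibited as strongly as
  the target itself, the dangerously non-selective case;
* ``random`` — uniform noise rows for bulk/property testing.

Generation is fully deterministic given the spec (including its seed), so
fixtures double as regression anchors.  Noise, when requested, is additive
Gaussian on the percent scale truncated to [0, 100]; cells are then masked
missing independently at ``missing_rate``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import InhibitionMatrix
from .scoring import TargetSet

ARCHETYPE_KINDS = ("clean_selective", "pan_weak", "few_strong", "random")

#: Fixture constants: on-target inhibition and the clean baseline off-target level.
DEFAULT_TARGET_INHIBITION = 90.0
DEFAULT_BASELINE = 2.0
DEFAULT_PAN_WEAK_LEVEL = 10.0
DEFAULT_FEW_STRONG_COUNT = 5
DEFAULT_FEW_STRONG_MAGNITUDE = 90.0


@dataclass(frozen=True)
class Archetype:
    """One synthetic compound: its label, kind, and kind-specific knobs."""

    label: str
    kind: str
    target_inhibition: float = DEFAULT_TARGET_INHIBITION
    baseline: float = DEFAULT_BASELINE
    level: float = DEFAULT_PAN_WEAK_LEVEL          # pan_weak off-target level
    count: int = DEFAULT_FEW_STRONG_COUNT           # few_strong off-target count
    magnitude: float = DEFAULT_FEW_STRONG_MAGNITUDE  # few_strong off-target strength

    def __post_init__(self):
        if self.kind not in ARCHETYPE_KINDS:
            raise ValidationError(f"unknown archetype kind {self.kind!r}")
        for name in ("target_inhibition", "baseline", "level", "magnitude"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")
        if self.kind == "few_strong" and not (2 <= self.count <= 10):
            raise ValidationError(f"few_strong count must be in [2, 10], got {self.count}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic screen: panel size, rows, noise, missingness."""

    n_kinases: int = 51
    archetypes: tuple[Archetype, ...] = ()
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_kinases < 2:
            raise ValidationError("panel needs at least 2 kinases")
        if not self.archetypes:
            raise ValidationError("spec needs at least one archetype row")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")


def default_archetype_trio() -> tuple[Archetype, ...]:
    """The standard three-row contrast fixture used throughout the tests."""
    return (
        Archetype("clean_selective", "clean_selective"),
        Archetype("pan_weak", "pan_weak"),
        Archetype("few_strong", "few_strong"),
    )


def _noiseless_row(arch: Archetype, targets: TargetSet, kinases: list[str],
                   rng: np.random.Generator) -> np.ndarray:
    target_set = set(targets)
    off_idx = [i for i, k in enumerate(kinases) if k not in target_set]
    if arch.kind == "few_strong" and arch.count > len(off_idx):
        raise ValidationError(
            f"few_strong count {arch.count} exceeds the {len(off_idx)} off-target slots"
        )
    row = np.empty(len(kinases))
    if arch.kind == "random":
        row[:] = rng.uniform(0.0, 100.0, size=len(kinases))
        return row
    row[:] = arch.baseline
    if arch.kind == "pan_weak":
        row[off_idx] = arch.level
    elif arch.kind == "few_strong":
        strong = rng.choice(off_idx, size=arch.count, replace=False)
        row[strong] = arch.magnitude
    for i, k in enumerate(kinases):
        if k in target_set:
            row[i] = arch.target_inhibition
    return row


def generate_matrix(spec: SyntheticSpec, targets: TargetSet) -> InhibitionMatrix:
    """Build the synthetic screen described by ``spec``.

    Kinase panel = the target names followed by numbered filler kinases
    (KIN001, ...).  One row per archetype.  The same spec (including seed)
    always yields a bitwise-identical matrix.
    """
    n_fill = spec.n_kinases - len(targets)
    if n_fill < 1:
        raise ValidationError("panel must contain at least one off-target kinase")
    kinases = list(targets) + [f"KIN{i:03d}" for i in range(1, n_fill + 1)]
    labels = [a.label for a in spec.archetypes]
    if len(set(labels)) != len(labels):
        raise ValidationError("archetype labels must be unique")

    rng = np.random.default_rng(spec.seed)
    rows = [_noiseless_row(a, targets, kinases, rng) for a in spec.archetypes]
    values = np.vstack(rows)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 100.0)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(values, index=labels, columns=kinases)
    return InhibitionMatrix(data=df, dataset_name=f"synthetic-seed{spec.seed}")


def archetype_expectations(spec: SyntheticSpec, targets: TargetSet) -> list[str]:
    """Closed-form expected ranking of the archetype labels, best first.

    Only valid for noiseless specs: each archetype's score S = G - P_b - P_n
    is evaluated analytically from its parameters (no matrix is built), and
    labels are returned sorted by descending S with the same tie-breaks as
    ranking (then descending G, then label).  ``random`` archetypes are not
    analytic and are rejected.
    """
    if spec.noise_sd > 0:
        raise ValidationError("closed-form expectations require noise_sd = 0")
    m = spec.n_kinases - len(targets)
    if m < 1:
        raise ValidationError("panel must contain at least one off-target kinase")

    def near_term(i: float, g: float) -> float:
        return 0.0 if i == 0.0 else i * i / (i + g)

    scored = []
    for arch in spec.archetypes:
        if arch.kind == "random":
            raise ValidationError("random archetypes have no closed-form expectation")
        g = arch.target_inhibition
        if arch.kind == "clean_selective":
            offs = [(arch.baseline, m)]
        elif arch.kind == "pan_weak":
            offs = [(arch.level, m)]
        else:  # few_strong
            offs = [(arch.magnitude, arch.count), (arch.baseline, m - arch.count)]
        p_b = sum(v * k for v, k in offs) / m
        p_n = sum(near_term(v, g) * k for v, k in offs) / m
        scored.append((arch.label, g - p_b - p_n, g))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [label for label, _, _ in scored]


def write_spec_sidecar(spec: SyntheticSpec, path: str | Path) -> None:
    """Record the generating parameters next to a written fixture, as JSON."""
    payload = dataclasses.asdict(spec)
    payload["archetypes"] = [dataclasses.asdict(a) for a in spec.archetypes]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def spec_from_dict(payload: dict) -> SyntheticSpec:
    """Rebuild a spec from a sidecar/config dictionary."""
    archetypes = tuple(Archetype(**a) for a in payload.get("archetypes", []))
    fields = {f.name for f in dataclasses.fields(SyntheticSpec)} - {"archetypes"}
    kwargs = {k: v for k, v in payload.items() if k in fields}
    return SyntheticSpec(archetypes=archetypes, **kwargs)
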