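"""Two-round dock/design/prediction filter cascade for binder design
metric tables.

The metrics themselves (interface area, shape complementarity, binding
energy, contact surfaces, AlphaFold confidence) come from upstream design
tools; this module only applies the threshold cascade.  All "above" /
"greater" / "less" comparisons are strict; "at least three" hydrogen bonds
is inclusive and "less than one" buried unsatisfied donor means zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DesignMetrics",
    "SchemaError",
    "dock_filter",
    "design_filter",
    "prediction_filter",
    "cascade",
    "DOCK_THRESHOLDS",
    "DESIGN_THRESHOLDS",
    "PREDICTION_THRESHOLDS",
]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class DesignMetrics:
    """One design's interface and prediction metrics."""

    design_id: str
    interface_area: float  # A^2
    shape_complementarity: float  # 0-1
    ddg: float  # Rosetta energy units; negative favourable
    contact_molecular_surface: float  # A^2
    contact_patch: float  # A^2
    hbonds_to_ligand: int
    buried_unsat: int
    plddt: float  # 0-100
    rmsd_to_design: float  # A
    ptm: float  # 0-1

    def __post_init__(self) -> None:
        if self.hbonds_to_ligand < 0 or self.buried_unsat < 0:
            raise SchemaError("counts must be non-negative")
        if not (0.0 <= self.shape_complementarity <= 1.0 and 0.0 <= self.ptm <= 1.0):
            raise SchemaError("shape complementarity and pTM must be in [0, 1]")
        if not (0.0 <= self.plddt <= 100.0):
            raise SchemaError("pLDDT must be in [0, 100]")


# stage thresholds: column -> (operator, value)
DOCK_THRESHOLDS = {
    "interface_area": (">", 900.0),
    "shape_complementarity": (">", 0.7),
    "ddg": ("<", -40.0),
    "contact_molecular_surface": (">", 480.0),
    "contact_patch": (">", 440.0),
}

DESIGN_THRESHOLDS = {
    "contact_molecular_surface": (">", 460.0),
    "ddg": ("<", -40.0),
    "hbonds_to_ligand": (">=", 3),
    "shape_complementarity": (">", 0.72),
    "interface_area": (">", 959.0),
    "buried_unsat": ("<", 1),
}

PREDICTION_THRESHOLDS = {
    "plddt": (">", 90.0),
    "rmsd_to_design": ("<", 1.1),
    "ptm": (">", 0.8),
}

_OPS = {
    ">": lambda col, v: col > v,
    "<": lambda col, v: col < v,
    ">=": lambda col, v: col >= v,
}


def _apply(rows: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    missing = [c for c in thresholds if c not in rows.columns]
    if missing:
        raise SchemaError(f"schema error: missing column(s) {', '.join(missing)}")
    mask = pd.Series(True, index=rows.index)
    for col, (op, value) in thresholds.items():
        mask &= _OPS[op](rows[col], value)
    return rows[mask]


def dock_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Round-one dock filter: interface area > 900 A^2, shape
    complementarity > 0.7, ddG < -40, contact molecular surface > 480 A^2,
    contact patch > 440 A^2."""
    return _apply(rows, DOCK_THRESHOLDS)


def design_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Post-interface-design filter: CMS > 460 A^2, ddG < -40, >= 3
    hydrogen bonds to the ligand, shape complementarity > 0.72, interface
    area > 959 A^2, and zero buried unsatisfied hydrogen-bond donors."""
    return _apply(rows, DESIGN_THRESHOLDS)


def prediction_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Structure-prediction filter: pLDDT > 90, prediction-to-design RMSD
    < 1.1 A, pTM > 0.8."""
    return _apply(rows, PREDICTION_THRESHOLDS)


def cascade(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run all three stages in order; returns survivors and per-stage
    survivor counts (including the input count)."""
    counts = {"input": len(rows)}
    out = dock_filter(rows)
    counts["dock"] = len(out)
    out = design_filter(out)
    counts["design"] = len(out)
    out = prediction_filter(out)
    counts["prediction"] = len(out)
    return out, counts
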