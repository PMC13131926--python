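"""Deterministic fixture generation: small loop libraries, an MC1-pattern
C2 ring, synthetic design-metric tables with ground-truth survivor counts,
and assay measurement tables with known outputs.

Everything is a pure function of the seed; fixture directories are
reproducible byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import (
    CytotoxMeasurement,
    PampaWell,
    classify_permeability,
    fraction_dimer_from_kd,
    pampa_pe,
    percent_cytotoxicity,
)
from .closure import BinWidths, ClosureTolerances, ClosureError, fuse, terminal_alignment
from .geometry import HBondCriteria
from .model import Macrocycle, count_cis_amides, nh_satisfaction_audit, parse_sequence
from .pdbio import write_pdb
from .sampling import RamachandranModel, SamplingError, sample_loop

__all__ = ["generate_fixtures", "make_c2_ring", "loop_index_frame", "synthetic_metrics_table", "scan_survivors", "FixtureError"]

MC1_SEQUENCE = "apL*F*apL*F*"


class FixtureError(RuntimeError):
    pass


def loop_index_frame(loops) -> pd.DataFrame:
    """Tabular index of a loop library: id, length, torsions, terminal
    transform and hydrogen-bond geometry, one row per loop."""
    rows = []
    for lp in loops:
        b = lp.terminal_hbond
        rows.append(
            {
                "loop_id": lp.loop_id,
                "n_internal": lp.n_internal,
                "torsions": ";".join(f"{v:.3f}" for v in lp.torsions.ravel()),
                "translation": ";".join(f"{v:.4f}" for v in lp.forward_transform.translation),
                "rotvec_deg": ";".join(f"{v:.4f}" for v in lp.forward_transform.rotvec_deg()),
                "hbond_donor": b.donor,
                "hbond_acceptor": b.acceptor,
                "ho_distance": round(b.ho_distance, 4),
                "nho_angle": round(b.nho_angle, 2),
                "hoc_angle": round(b.hoc_angle, 2),
            }
        )
    return pd.DataFrame(rows)


def make_c2_ring(
    seed: int,
    cis_probability: float = 0.3,
    want_cis: int = 2,
    max_slots: int = 4000,
    criteria: HBondCriteria = HBondCriteria(),
    tolerances: ClosureTolerances = ClosureTolerances(),
) -> Macrocycle:
    """Search n=3 loop substreams for a self-closing loop and return the
    C2-symmetrized 8-ring carrying the MC1 sequence.

    Slots are scanned in order, so the result is a pure function of the
    seed.  Rings whose cis-amide count equals ``want_cis`` (two, matching
    the MC1 crystal) are preferred; if none appears within the slot budget
    the first C2 ring found is returned.
    """
    rama = RamachandranModel(cis_probability=cis_probability)
    fallback: Macrocycle | None = None
    for slot in range(max_slots):
        try:
            loop = sample_loop(3, rama, seed, criteria, max_draws=20_000, slot=slot)
        except SamplingError:
            continue
        _, rmsd = terminal_alignment(loop, loop)
        if rmsd > tolerances.terminal_rmsd:
            continue
        try:
            ring = fuse(loop, loop, criteria, tolerances, symmetrize=True)
        except ClosureError:
            continue
        mc = ring.with_sequence(parse_sequence(MC1_SEQUENCE))
        if count_cis_amides(mc) == want_cis:
            return mc
        if fallback is None:
            fallback = mc
    if fallback is not None:
        return fallback
    raise FixtureError("no self-closing n=3 loop found within the slot budget")


def synthetic_metrics_table(rng: np.random.Generator, n_rows: int) -> pd.DataFrame:
    """Synthetic design-metric rows scattered around the filter thresholds
    so that every stage removes some rows."""
    return pd.DataFrame(
        {
            "design_id": [f"d{i:04d}" for i in range(n_rows)],
            "interface_area": rng.uniform(700, 1300, n_rows).round(1),
            "shape_complementarity": rng.uniform(0.55, 0.9, n_rows).round(3),
            "ddg": rng.uniform(-70, -20, n_rows).round(2),
            "contact_molecular_surface": rng.uniform(350, 700, n_rows).round(1),
            "contact_patch": rng.uniform(300, 650, n_rows).round(1),
            "hbonds_to_ligand": rng.integers(0, 7, n_rows),
            "buried_unsat": rng.integers(0, 3, n_rows),
            "plddt": rng.uniform(80, 100, n_rows).round(2),
            "rmsd_to_design": rng.uniform(0.3, 2.0, n_rows).round(3),
            "ptm": rng.uniform(0.6, 0.95, n_rows).round(3),
        }
    )


def scan_survivors(rows: pd.DataFrame) -> dict[str, int]:
    """Independent brute-force row scan of the cascade (plain Python
    comparisons, no pandas filtering) used for fixture manifests."""
    dock = design = prediction = 0
    for r in rows.to_dict("records"):
        if not (
            r["interface_area"] > 900 and r["shape_complementarity"] > 0.7
            and r["ddg"] < -40 and r["contact_molecular_surface"] > 480
            and r["contact_patch"] > 440
        ):
            continue
        dock += 1
        if not (
            r["contact_molecular_surface"] > 460 and r["ddg"] < -40
            and r["hbonds_to_ligand"] >= 3 and r["shape_complementarity"] > 0.72
            and r["interface_area"] > 959 and r["buried_unsat"] < 1
        ):
            continue
        design += 1
        if r["plddt"] > 90 and r["rmsd_to_design"] < 1.1 and r["ptm"] > 0.8:
            prediction += 1
    return {"input": len(rows), "dock": dock, "design": design, "prediction": prediction}


def _assay_tables(rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    wells = []
    for i in range(6):
        c0 = 20.0
        ca = float(rng.uniform(0.0, 4.0))
        cd = float(rng.uniform(8.0, c0 - ca))
        w = PampaWell(cd_t=round(cd, 3), ca_t=round(ca, 3), c0=c0)
        res = pampa_pe(w)
        wells.append(
            {
                "well": f"w{i}", "cd_t": w.cd_t, "ca_t": w.ca_t, "c0": w.c0,
                "vd": w.vd, "va": w.va, "area": w.area, "t": w.t,
                "expected_ceq": res.ceq, "expected_retention": res.retention,
                "expected_pe": res.pe, "expected_class": classify_permeability(res.pe),
            }
        )
    dimer = []
    for kd in (0.1, 0.4, 2.0, 20.0):
        for p in (2.0, 9.4, 50.0):
            eq = fraction_dimer_from_kd(kd, p)
            dimer.append(
                {"kd_nM": kd, "p_total_nM": p, "expected_fd": eq.fraction_dimer,
                 "expected_monomer_nM": eq.monomer, "expected_dimer_nM": eq.dimer}
            )
    cyto = []
    for i in range(5):
        bg = float(rng.uniform(100, 200))
        mx = bg + float(rng.uniform(4000, 9000))
        ex = bg + (mx - bg) * float(rng.uniform(0, 1))
        m = CytotoxMeasurement(experimental=round(ex, 1), background=round(bg, 1), maximum=round(mx, 1))
        cyto.append(
            {"sample": f"s{i}", "experimental": m.experimental, "background": m.background,
             "maximum": m.maximum, "expected_percent": percent_cytotoxicity(m)}
        )
    return pd.DataFrame(wells), pd.DataFrame(dimer), pd.DataFrame(cyto)


def generate_fixtures(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write a deterministic fixture set of the requested kind into
    ``outdir`` and return the created paths.

    Kinds: ``loops`` (small per-length loop libraries + index table),
    ``mc1_ring`` (C2 8-ring PDB with the MC1 sequence + audit manifest),
    ``metrics`` (synthetic design-metric table + survivor-count manifest),
    ``assays`` (PAMPA / dimer / cytotoxicity tables with expected values),
    or ``all``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind not in {"loops", "mc1_ring", "metrics", "assays", "all"}:
        raise FixtureError(f"unknown fixture kind: {kind}")

    if kind in ("loops", "all"):
        from .sampling import generate_library

        lib = generate_library({3: 5, 4: 3, 5: 2}, seed=seed)
        for lp in lib.loops:
            p = outdir / f"loop_{lp.loop_id}.pdb"
            write_pdb(p, lp)
            written.append(p)
        idx = outdir / "loop_index.tsv"
        loop_index_frame(lib.loops).to_csv(idx, sep="\t", index=False)
        written.append(idx)

    if kind in ("mc1_ring", "all"):
        mc = make_c2_ring(seed)
        p = outdir / "mc1_ring.pdb"
        write_pdb(p, mc)
        manifest = {
            "sequence": MC1_SEQUENCE,
            "ring_length": len(mc),
            "transannular_hbonds": len(mc.transannular_hbonds),
            "unsatisfied_nh": nh_satisfaction_audit(mc),
            "cis_amides": count_cis_amides(mc),
        }
        mp = outdir / "mc1_ring.json"
        mp.write_text(json.dumps(manifest, indent=1))
        written += [p, mp]

    if kind in ("metrics", "all"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        table = synthetic_metrics_table(rng, 400)
        tp = outdir / "design_metrics.tsv"
        table.to_csv(tp, sep="\t", index=False)
        mp = outdir / "design_metrics.json"
        mp.write_text(json.dumps(scan_survivors(table), indent=1))
        written += [tp, mp]

    if kind in ("assays", "all"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
        pampa, dimer, cyto = _assay_tables(rng)
        for name, df in (("pampa_wells", pampa), ("dimer_points", dimer), ("cytotox", cyto)):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
    return written
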