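"""Ambiguous interaction restraints (AIRs) from CSP maps plus accessibility.

Active residues are those with a significant CSP that are also solvent
accessible; passive residues are accessible residues neighbouring an active
one.  Each active residue yields one ambiguous ``assign`` restraint to the
partner's active+passive set, in the CNS/HADDOCK dialect.  Docking cluster
scores are post-processed into z-scores (standard deviations from the mean
over all clusters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

from .csp_mapping import CSPProfile, CLASS_ABOVE_SIGMA, CLASS_ABOVE_2SIGMA

__all__ = [
    "SurfaceAccessibility",
    "PartnerRestraints",
    "RestraintSet",
    "compute_accessibility",
    "select_active_passive",
    "write_air_restraints",
    "parse_air_restraints",
    "write_restraint_variants",
    "cluster_z_scores",
    "MAX_ASA",
]

# Maximum accessible surface areas (A^2) for X in an extended Gly-X-Gly
# tripeptide (Miller et al. 1987), used to normalise per-residue heavy-atom
# Shrake-Rupley areas into relative accessibilities.
MAX_ASA: dict[str, float] = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLU": 183.0, "GLN": 189.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

# Heavy-atom counts of complete standard residues (no hydrogens, incl. O).
_HEAVY_ATOMS: dict[str, int] = {
    "GLY": 4, "ALA": 5, "SER": 6, "CYS": 6, "THR": 7, "VAL": 7, "PRO": 7,
    "LEU": 8, "ILE": 8, "ASN": 8, "ASP": 8, "MET": 8, "GLN": 9, "GLU": 9,
    "LYS": 9, "HIS": 10, "ARG": 11, "PHE": 11, "TYR": 12, "TRP": 14,
}

DEFAULT_ACCESS_CUTOFF = 0.40  # relative accessibility for "solvent accessible"
DEFAULT_NEIGHBOUR_CUTOFF = 6.5  # A, heavy-atom distance for passive selection


@dataclass
class SurfaceAccessibility:
    """Relative per-residue solvent accessibility of one model.

    ``table`` columns: chain, residue_number, residue_name, sasa,
    rel_access (clipped to [0, 1]), incomplete (bool, atoms missing).
    """

    table: pd.DataFrame
    probe_radius: float

    def rel(self, residue_number: int, chain: str | None = None) -> float:
        sel = self.table["residue_number"] == residue_number
        if chain is not None:
            sel &= self.table["chain"] == chain
        hit = self.table.loc[sel]
        if hit.empty:
            raise KeyError(f"residue {residue_number} not in structure")
        return float(hit["rel_access"].iloc[0])

    def accessible_residues(self, cutoff: float, chain: str | None = None) -> list[int]:
        sel = self.table["rel_access"] >= cutoff
        if chain is not None:
            sel &= self.table["chain"] == chain
        return self.table.loc[sel, "residue_number"].tolist()


def _load_model(structure, model_index: int = 0):
    """Accept a PDB path or a Bio.PDB Structure/Model."""
    if isinstance(structure, (str, Path)):
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("input", str(structure))
    if hasattr(structure, "get_models"):  # Structure
        models = list(structure.get_models())
        return models[model_index]
    return structure  # already a Model


def compute_accessibility(
    structure, probe_radius: float = 1.4, model_index: int = 0, n_points: int = 960
) -> SurfaceAccessibility:
    """Shrake-Rupley accessible surface per residue, normalised by MAX_ASA.

    Residues with missing heavy atoms are flagged (``incomplete``); their
    accessibility is computed from the atoms present.  Only standard amino
    acids are tabulated; waters and heteroatoms are ignored.
    """
    model = _load_model(structure, model_index)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")
    rows = []
    for chain in model:
        for res in chain:
            name = res.get_resname().strip()
            if name not in MAX_ASA:
                continue
            n_heavy = sum(1 for a in res if a.element != "H")
            sasa = float(res.sasa)
            rows.append(
                {
                    "chain": chain.id,
                    "residue_number": int(res.id[1]),
                    "residue_name": name,
                    "sasa": sasa,
                    "rel_access": min(sasa / MAX_ASA[name], 1.0),
                    "incomplete": n_heavy < _HEAVY_ATOMS[name],
                }
            )
    if not rows:
        raise ValueError("no standard amino-acid residues in structure")
    return SurfaceAccessibility(table=pd.DataFrame(rows), probe_radius=probe_radius)


@dataclass
class PartnerRestraints:
    """Active/passive residue lists for one docking partner."""

    segid: str
    active: list[int]
    passive: list[int]

    def __post_init__(self) -> None:
        self.active = sorted(int(r) for r in self.active)
        self.passive = sorted(int(r) for r in self.passive)
        overlap = set(self.active) & set(self.passive)
        if overlap:
            raise ValueError(f"active/passive overlap: {sorted(overlap)}")


@dataclass
class RestraintSet:
    """AIR definition for a two-partner docking run."""

    partner_a: PartnerRestraints
    partner_b: PartnerRestraints
    distance: float = 2.0
    lower: float = 0.0
    upper: float = 0.0


def select_active_passive(
    profile: CSPProfile,
    access: SurfaceAccessibility,
    structure,
    access_cutoff: float = DEFAULT_ACCESS_CUTOFF,
    neighbour_cutoff: float = DEFAULT_NEIGHBOUR_CUTOFF,
    offset: int | Mapping[int, int] = 0,
    chain: str | None = None,
    segid: str = "A",
    significance: str = CLASS_ABOVE_SIGMA,
    model_index: int = 0,
) -> PartnerRestraints:
    """Active = significant CSP and accessible; passive = accessible
    neighbours (any heavy atom within ``neighbour_cutoff`` of any active
    heavy atom), excluding actives.

    ``offset`` maps profile residue numbers onto structure numbering,
    either a constant shift or an explicit map.  A significant residue that
    cannot be found in the structure raises, pointing at the mismatch.
    """
    if significance == CLASS_ABOVE_2SIGMA:
        significant = profile.residues_in_class(CLASS_ABOVE_2SIGMA)
    else:
        significant = profile.significant_residues

    if isinstance(offset, Mapping):
        def to_struct(r: int) -> int:
            return int(offset[r]) if r in offset else int(r)
    else:
        def to_struct(r: int) -> int:
            return int(r) + int(offset)

    struct_nums = set(access.table["residue_number"]) if chain is None else set(
        access.table.loc[access.table["chain"] == chain, "residue_number"]
    )
    mapped = {}
    for r in significant:
        sr = to_struct(r)
        if sr not in struct_nums:
            raise ValueError(
                f"residue numbering mismatch: profile residue {r} maps to {sr}, "
                "absent from the structure; supply an offset map"
            )
        mapped[r] = sr

    active = sorted(
        sr for sr in mapped.values() if access.rel(sr, chain) >= access_cutoff
    )

    # heavy-atom coordinates per residue
    model = _load_model(structure, model_index)
    coords: dict[int, np.ndarray] = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.get_resname().strip() not in MAX_ASA:
                continue
            xyz = [a.coord for a in res if a.element != "H"]
            if xyz:
                coords[int(res.id[1])] = np.asarray(xyz, dtype=float)

    active_xyz = (
        np.concatenate([coords[r] for r in active]) if active else np.empty((0, 3))
    )
    passive = []
    for r in access.accessible_residues(access_cutoff, chain):
        if r in active or r not in coords or active_xyz.size == 0:
            continue
        d = np.linalg.norm(coords[r][:, None, :] - active_xyz[None, :, :], axis=-1)
        if d.min() <= neighbour_cutoff:
            passive.append(r)
    return PartnerRestraints(segid=segid, active=active, passive=sorted(passive))


# ---------------------------------------------------------------------------
# restraint file emission (CNS/HADDOCK assign dialect)


def _format_block(active: int, segid: str, partner: PartnerRestraints,
                  distance: float, lower: float, upper: float) -> str:
    targets = partner.active + partner.passive
    lines = [f"assign ( resid {active} and segid {segid} )", "       ("]
    for i, tr in enumerate(sorted(targets)):
        if i:
            lines.append("     or")
        lines.append(f"        ( resid {tr} and segid {partner.segid} )")
    lines.append(f"       ) {distance:.1f} {lower:.1f} {upper:.1f}")
    return "\n".join(lines)


def write_air_restraints(rset: RestraintSet, path: str | Path) -> str:
    """Emit one ambiguous assign statement per active residue of each
    partner; output is byte-stable for identical input.  Returns the text."""
    a, b = rset.partner_a, rset.partner_b
    if not a.active and not b.active:
        raise ValueError("both partners have empty active sets")
    blocks = []
    for act in a.active:
        blocks.append(_format_block(act, a.segid, b, rset.distance, rset.lower, rset.upper))
    for act in b.active:
        blocks.append(_format_block(act, b.segid, a, rset.distance, rset.lower, rset.upper))
    text = "\n!\n".join(blocks) + "\n"
    Path(path).write_text(text)
    return text


_ASSIGN_RE = re.compile(
    r"assign\s*\(\s*resid\s+(\d+)\s+and\s+segid\s+(\w+)\s*\)\s*"
    r"\((.*?)\)\s*([\d.]+)\s+([\d.]+)\s+([\d.]+)",
    re.S,
)
_TARGET_RE = re.compile(r"resid\s+(\d+)\s+and\s+segid\s+(\w+)")


def parse_air_restraints(path: str | Path) -> RestraintSet:
    """Recover a RestraintSet from an emitted restraint file."""
    text = Path(path).read_text()
    actives: dict[str, list[int]] = {}
    listed: dict[str, set[int]] = {}
    dist = lower = upper = None
    for m in _ASSIGN_RE.finditer(text):
        resid, segid, body, d, lo, up = m.groups()
        actives.setdefault(segid, []).append(int(resid))
        for tm in _TARGET_RE.finditer(body):
            tr, tseg = tm.groups()
            listed.setdefault(tseg, set()).add(int(tr))
        dist, lower, upper = float(d), float(lo), float(up)
    if dist is None:
        raise ValueError("no assign statements found")
    segids = sorted(set(actives) | set(listed))
    if len(segids) > 2:
        raise ValueError(f"more than two segids present: {segids}")
    while len(segids) < 2:
        segids.append("B" if "B" not in segids else "A")
    partners = []
    for seg in segids:
        act = sorted(set(actives.get(seg, [])))
        passive = sorted(listed.get(seg, set()) - set(act))
        partners.append(PartnerRestraints(segid=seg, active=act, passive=passive))
    return RestraintSet(partners[0], partners[1], dist, lower, upper)


def write_restraint_variants(
    rset: RestraintSet,
    directory: str | Path,
    k: int,
    omit_fraction: float,
    seed: int,
) -> list[Path]:
    """Optionally emit k seeded variant files, each omitting a random
    fraction of the assign blocks (mirrors docking engines that delete a
    fraction of restraints per run).  Off by default in the pipeline."""
    if not 0 <= omit_fraction < 1:
        raise ValueError("omit_fraction must be in [0, 1)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    pooled = [("a", r) for r in rset.partner_a.active] + [
        ("b", r) for r in rset.partner_b.active
    ]
    n_keep = max(1, int(round(len(pooled) * (1 - omit_fraction))))
    for i in range(k):
        keep_idx = sorted(rng.choice(len(pooled), size=n_keep, replace=False))
        keep = [pooled[j] for j in keep_idx]
        sub = RestraintSet(
            PartnerRestraints(
                rset.partner_a.segid,
                [r for s, r in keep if s == "a"],
                rset.partner_a.passive,
            ),
            PartnerRestraints(
                rset.partner_b.segid,
                [r for s, r in keep if s == "b"],
                rset.partner_b.passive,
            ),
            rset.distance,
            rset.lower,
            rset.upper,
        )
        p = directory / f"airs_variant_{i}.tbl"
        write_air_restraints(sub, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# docking cluster z-scores


def cluster_z_scores(table, estimator: str = "population") -> pd.DataFrame:
    """z_i = (score_i - mean) / sd over all docking clusters.

    Accepts a DataFrame with ``cluster``/``score`` columns or a plain score
    sequence.  More negative z means better ranked (lower energy score).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        if "score" not in df.columns:
            raise ValueError("table needs a 'score' column")
        if "cluster" not in df.columns:
            df.insert(0, "cluster", range(1, len(df) + 1))
    else:
        scores = list(table)
        df = pd.DataFrame({"cluster": range(1, len(scores) + 1), "score": scores})
    if len(df) < 2:
        raise ValueError("need at least 2 clusters for z-scores")
    scores = df["score"].to_numpy(dtype=float)
    sd = scores.std(ddof=0 if estimator == "population" else 1)
    if sd == 0:
        raise ValueError("zero variance: all cluster scores identical")
    df["z"] = (scores - scores.mean()) / sd
    return df
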