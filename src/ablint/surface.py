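"""Per-residue solvent accessibility and the surface low-risk flag.

Water drives most chemical degradation, so a liability motif that is buried
in the folded Fv is less likely to react.  Given a paired heavy/light
structural model with residues numbered in the IMGT scheme, this module
computes per-residue absolute solvent-accessible surface area (SASA) with a
Shrake-Rupley sphere-sampling algorithm over heavy atoms, normalizes by the
residue type's theoretical maximum accessible area, and classifies each
position as *exposed* (relative SASA strictly above 7.5%) or *buried*.

A motif whose residues are all buried is flagged low-risk; mixed motifs are
*partial*; residues without structure coverage (or position-less hits such
as a missing conserved cysteine) are *unknown*.

The sampling point set is a deterministic golden-section spiral, so results
are bit-stable across runs; relative SASA is capped at 1 because the
theoretical maxima are Gly-X-Gly tripeptide values that an isolated residue
can exceed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .detect import LiabilityHit
from .flags import FlagConfig
from .numbering import ImgtPosition

__all__ = [
    "StructureModel",
    "ResidueExposure",
    "VDW_RADII",
    "MAX_ASA",
    "sphere_points",
    "compute_sasa",
    "classify_exposure",
    "residue_exposures",
    "flag_surface",
]

# Heavy-atom van der Waals radii (A); hydrogens are ignored.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70


def _load_max_asa() -> tuple[dict[str, float], dict[str, str]]:
    one, three_to_one = {}, {}
    text = (
        resources.files("ablint.data").joinpath("max_asa.tsv").read_text("utf-8")
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        r1, r3, area = line.split("\t")
        one[r1] = float(area)
        three_to_one[r3] = r1
    return one, three_to_one


MAX_ASA, THREE_TO_ONE = _load_max_asa()
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ResidueRef:
    """A structure residue mapped to an IMGT position on one chain role."""

    role: str  # "H" or "L"
    position: ImgtPosition
    restype: str  # one-letter code
    atom_indices: list[int]


@dataclass
class StructureModel:
    """Atoms of a (toy or modeled) Fv with residue -> IMGT mapping.

    ``coords``/``radii`` cover every atom, including occluder atoms that
    belong to no mapped residue (they still block solvent).
    """

    coords: np.ndarray  # (n_atoms, 3), Angstrom
    radii: np.ndarray  # (n_atoms,)
    residues: list[ResidueRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.radii) != len(self.coords):
            raise ValueError("radii/coords length mismatch")
        for res in self.residues:
            if not res.atom_indices:
                raise ValueError(
                    f"residue {res.role}{res.position} has no heavy atoms"
                )

    @property
    def roles(self) -> set[str]:
        return {r.role for r in self.residues}

    def subset(self, role: str) -> "StructureModel":
        """Atoms and residues of a single chain role (for isolated-chain SASA)."""
        keep = [r for r in self.residues if r.role == role]
        idx = sorted({i for r in keep for i in r.atom_indices})
        remap = {old: new for new, old in enumerate(idx)}
        return StructureModel(
            coords=self.coords[idx],
            radii=self.radii[idx],
            residues=[
                ResidueRef(r.role, r.position, r.restype,
                           [remap[i] for i in r.atom_indices])
                for r in keep
            ],
        )

    # -- PDB I/O (gemmi) ----------------------------------------------------

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        role_of_chain: dict[str, str] | None = None,
    ) -> "StructureModel":
        """Read a PDB file; residue seqid + icode is taken as the IMGT
        position (the ABodyBuilder2 convention).  Chains named H/L map to
        the two roles by default; atoms of any other chain occlude but are
        not mapped.  Hydrogens are skipped."""
        role_of_chain = role_of_chain or {"H": "H", "L": "L", "K": "L"}
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        coords: list[list[float]] = []
        radii: list[float] = []
        residues: list[ResidueRef] = []
        model = st[0]
        for chain in model:
            role = role_of_chain.get(chain.name)
            for res in chain:
                idx: list[int] = []
                for atom in res:
                    if atom.element.name == "H":
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(VDW_RADII.get(atom.element.name, DEFAULT_RADIUS))
                    idx.append(len(coords) - 1)
                if role is None or not idx:
                    continue
                restype = THREE_TO_ONE.get(res.name)
                if restype is None:
                    continue  # unmapped residue: occludes only
                icode = res.seqid.icode.strip() or None
                try:
                    pos = ImgtPosition(res.seqid.num, icode)
                except ValueError:
                    continue
                residues.append(ResidueRef(role, pos, restype, idx))
        if not coords:
            raise ValueError(f"{path}: no heavy atoms read")
        return cls(np.array(coords), np.array(radii), residues)

    def to_pdb(self, path: str | Path) -> None:
        """Write atoms as a minimal PDB (CA-level toy structures round-trip)."""
        mapped: dict[int, tuple[str, ImgtPosition, str]] = {}
        for res in self.residues:
            for i in res.atom_indices:
                mapped[i] = (res.role, res.position, res.restype)
        with open(path, "w", encoding="utf-8") as fh:
            serial = 0
            for i, (x, y, z) in enumerate(self.coords):
                serial += 1
                if i in mapped:
                    role, pos, restype = mapped[i]
                    resname = ONE_TO_THREE[restype]
                    record, name, chain = "ATOM  ", " CA ", role
                    seq, icode = pos.number, pos.insertion or " "
                    element = " C"
                else:
                    record, name, chain = "HETATM", " DUM", "X"
                    resname = "DUM"
                    seq, icode = (serial % 9999) + 1, " "
                    element = " C"
                fh.write(
                    f"{record}{serial:5d} {name} {resname:>3s}"
                    f" {chain}{seq:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element}\n"
                )
            fh.write("END\n")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of *n* points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_points: int,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Shrake-Rupley accessible area per atom.

    Every atom occludes, but area is only evaluated for ``targets``
    (default: all atoms); pure occluders (e.g. dummy shells) are skipped.
    """
    unit = sphere_points(n_points)
    n = len(coords)
    ext = radii + probe_radius
    out = np.zeros(n)
    # pairwise distances once; toy/Fv structure sizes keep this cheap
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    for i in (range(n) if targets is None else np.asarray(targets)):
        neighbors = np.where((dist[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        if len(neighbors) == 0:
            out[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        pts = coords[i] + ext[i] * unit
        diffs = pts[:, None, :] - coords[neighbors][None, :, :]
        blocked = (diffs**2).sum(axis=2) < ext[neighbors][None, :] ** 2
        accessible = ~blocked.any(axis=1)
        out[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    return out


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, ImgtPosition], float]:
    """Per-residue absolute SASA (A^2) of the full complex.

    All atoms occlude (including unmapped occluders); only mapped residues
    are reported.  Deterministic for a given ``n_points``.
    """
    if len(structure.coords) == 0:
        raise ValueError("empty structure")
    targets = np.array(
        sorted({i for res in structure.residues for i in res.atom_indices}),
        dtype=int,
    ) if structure.residues else None
    per_atom = _atom_sasa(
        structure.coords, structure.radii, probe_radius, n_points, targets
    )
    return {
        (res.role, res.position): float(per_atom[res.atom_indices].sum())
        for res in structure.residues
    }


def classify_exposure(rel_sasa: float, cfg: FlagConfig | None = None) -> str:
    """``exposed`` iff relative SASA strictly exceeds the threshold."""
    if rel_sasa < 0:
        raise ValueError(f"negative relative SASA {rel_sasa}")
    cfg = cfg or FlagConfig()
    return "exposed" if rel_sasa > cfg.exposure_threshold else "buried"


@dataclass(frozen=True)
class ResidueExposure:
    role: str
    position: ImgtPosition
    restype: str
    abs_sasa: float
    rel_sasa: float
    exposure_class: str


def residue_exposures(
    structure: StructureModel,
    cfg: FlagConfig | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, ImgtPosition], ResidueExposure]:
    """Absolute and relative SASA plus burial class for every mapped residue."""
    cfg = cfg or FlagConfig()
    abs_sasa = compute_sasa(structure, probe_radius, n_points)
    out = {}
    for res in structure.residues:
        a = abs_sasa[(res.role, res.position)]
        rel = min(1.0, a / MAX_ASA[res.restype])
        out[(res.role, res.position)] = ResidueExposure(
            role=res.role,
            position=res.position,
            restype=res.restype,
            abs_sasa=a,
            rel_sasa=rel,
            exposure_class=classify_exposure(rel, cfg),
        )
    return out


def flag_surface(
    hit: LiabilityHit,
    exposures: dict[tuple[str, ImgtPosition], ResidueExposure],
    role: str,
) -> str:
    """Burial class of a whole motif.

    ``buried`` if every residue is buried, ``exposed`` if every residue is
    exposed, ``partial`` if mixed, ``unknown`` if the hit has no residues
    (missing-cysteine) or any residue lacks structure coverage.
    """
    if not hit.residues:
        return "unknown"
    classes = []
    for pos, _ in hit.residues:
        exp = exposures.get((role, pos))
        if exp is None:
            return "unknown"
        classes.append(exp.exposure_class)
    if all(c == "buried" for c in classes):
        return "buried"
    if all(c == "exposed" for c in classes):
        return "exposed"
    return "partial"


def write_exposure_table(
    exposures: dict[tuple[str, ImgtPosition], ResidueExposure],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "imgt_position", "restype",
                    "abs_sasa", "rel_sasa", "class"])
        for (role, pos), exp in exposures.items():
            w.writerow([role, str(pos), exp.restype,
                        f"{exp.abs_sasa:.4f}", f"{exp.rel_sasa:.4f}",
                        exp.exposure_class])
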