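"""Structure handling: chain extraction, sequence-structure alignment,
solvent accessibility, and RSA-modulated scores.

The chain of interest is read from a PDB file (first model, waters and
unmappable heteroatoms dropped, common modified residues mapped to their
standard parent). Its sequence is aligned globally to the query with an
affine gap scheme (match 1.0, mismatch -3.0, gap open -2.5, gap extension
and terminal gaps -2.0), giving a strictly monotone position mapping.

Relative solvent accessibility is computed with the Shrake-Rupley algorithm
(probe radius 1.4 Angstrom, 100 sampling points per atom sphere), summed per
residue and normalised by the theoretical maximum ASA of the residue type
(Tien et al. 2013). For a multimeric file both contexts are computed: the
chain in its complex (complexed) and stripped of its partners (free).

The structure-aware score down-weights exposed residues:

    score_rsa = score_evol * (1 - min(RSA, 100) / 100)

so a fully buried residue keeps its evolutionary score and a fully exposed
one is zeroed. Query positions without a structural counterpart are NaN.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.Structure import Structure

from .alphabet import (
    MAX_ASA_TABLE_NAME,
    MAX_ASA_TIEN_2013_THEORETICAL,
    residue_one_letter,
)
from .errors import StructureError
from .landscape import MutationalLandscape

PROBE_RADIUS = 1.4  # Angstrom, water probe
N_SPHERE_POINTS = 100

ALIGN_MATCH = 1.0
ALIGN_MISMATCH = -3.0
ALIGN_GAP_OPEN = -2.5
ALIGN_GAP_EXTEND = -2.0
ALIGN_TERMINAL_GAP = -2.0

UNMAPPED_BFACTOR = -99.0


@dataclass(frozen=True)
class ResidueRecord:
    resnum: int  # author residue number
    icode: str
    resname: str  # original 3-letter name
    one_letter: str
    bfactor: float  # mean over atoms; pLDDT for AlphaFold models


@dataclass
class ChainStructure:
    """A cleaned protein chain plus handles for SASA and export.

    ``model`` holds every cleaned chain of the file (for complexed-context
    accessibility); ``chain`` is the chain of interest within it.
    """

    chain_id: str
    residues: list[ResidueRecord]
    source: str  # "pdb_experimental" or "alphafold_model"
    model: Model = field(repr=False, default=None)

    @property
    def chain(self) -> Chain:
        return self.model[self.chain_id]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def n_chains(self) -> int:
        return len(list(self.model))

    @property
    def is_multimer(self) -> bool:
        return self.n_chains > 1

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([r.bfactor for r in self.residues])

    def plddt(self) -> np.ndarray | None:
        """Per-residue pLDDT, only when the file is declared an AlphaFold
        model; experimental B-factors are never interpreted as confidence."""
        return self.bfactors if self.source == "alphafold_model" else None


@dataclass(frozen=True)
class SeqStructMapping:
    """Monotone correspondence between query positions and chain residues."""

    pairs: tuple[tuple[int, int], ...]  # (query position 1-based, chain index 0-based)
    unaligned_query_positions: frozenset[int]
    alignment_score: float
    identity: float  # matches / aligned pairs


@dataclass
class RsaProfile:
    """Per-residue accessibility of the chain of interest.

    ``rsa_*`` are percentages (uncapped; capping at 100 happens only inside
    the structure-aware score). ``asa_*`` keep the raw Shrake-Rupley areas
    in Angstrom^2 for audit. ``rsa_complexed`` equals ``rsa_free`` for a
    monomeric input.
    """

    asa_free: np.ndarray
    asa_complexed: np.ndarray
    rsa_free: np.ndarray
    rsa_complexed: np.ndarray
    max_asa_table: str = MAX_ASA_TABLE_NAME


def read_chain(
    path: str | Path, chain_id: str = "A", alphafold_model: bool = False
) -> ChainStructure:
    """Parse a PDB file and extract one cleaned protein chain.

    First model only; waters and unmappable heteroatoms are dropped; common
    modified residues (MSE, SEP, TPO, PTR, MLY, M3L, HYP, ...) are mapped to
    their standard parent. Disordered atoms keep their highest-occupancy
    conformer. Raises :class:`StructureError` for a missing chain or a chain
    with no standard residues.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("input", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"could not parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no models in {path}")
    model = models[0]

    clean_model = Model(0)
    kept_ids = []
    for chain in model:
        clean = Chain(chain.id)
        for residue in chain:
            if residue_one_letter(residue.get_resname()) is None:
                continue
            if not list(residue.get_atoms()):
                continue
            clean.add(residue.copy())
        if len(clean):
            clean_model.add(clean)
            kept_ids.append(chain.id)
    if chain_id not in kept_ids:
        raise StructureError(
            f"chain {chain_id!r} not found or has no standard residues "
            f"(protein chains present: {kept_ids})"
        )

    records = []
    for residue in clean_model[chain_id]:
        one = residue_one_letter(residue.get_resname())
        bf = float(np.mean([a.get_bfactor() for a in residue.get_atoms()]))
        _, resnum, icode = residue.get_id()
        records.append(
            ResidueRecord(
                resnum=int(resnum),
                icode=icode.strip(),
                resname=residue.get_resname(),
                one_letter=one,
                bfactor=bf,
            )
        )
    return ChainStructure(
        chain_id=chain_id,
        residues=records,
        source="alphafold_model" if alphafold_model else "pdb_experimental",
        model=clean_model,
    )


def make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_internal_gap_score = ALIGN_GAP_OPEN
    aligner.extend_internal_gap_score = ALIGN_GAP_EXTEND
    aligner.open_end_gap_score = ALIGN_TERMINAL_GAP
    aligner.extend_end_gap_score = ALIGN_TERMINAL_GAP
    return aligner


def align_query_to_chain(query_seq: str, chain_seq: str) -> SeqStructMapping:
    """Global affine alignment of the query to the chain sequence.

    Gap costs: first internal gap residue -2.5, each further residue -2.0;
    every terminal gap residue -2.0. Of the optimal paths, the aligner's
    first reported one is used (a fixed deterministic tie-break). Aligned
    non-gap column pairs become mapping pairs, mismatched ones included —
    the structure may be an isoform or homologue of the query.
    """
    if not query_seq or not chain_seq:
        raise StructureError("cannot align empty sequences")
    aligner = make_aligner()
    alignment = aligner.align(query_seq, chain_seq)[0]
    pairs = []
    matches = 0
    for (qs, qe), (cs, ce) in zip(*alignment.aligned):
        for off in range(qe - qs):
            qpos0, cpos0 = int(qs) + off, int(cs) + off
            pairs.append((qpos0 + 1, cpos0))
            if query_seq[qpos0] == chain_seq[cpos0]:
                matches += 1
    aligned_q = {p for p, _ in pairs}
    unaligned = frozenset(
        p for p in range(1, len(query_seq) + 1) if p not in aligned_q
    )
    return SeqStructMapping(
        pairs=tuple(pairs),
        unaligned_query_positions=unaligned,
        alignment_score=float(alignment.score),
        identity=matches / len(pairs) if pairs else 0.0,
    )


def _residue_sasa(model: Model, chain_id: str) -> np.ndarray:
    sr = ShrakeRupley(probe_radius=PROBE_RADIUS, n_points=N_SPHERE_POINTS)
    sr.compute(model, level="R")
    return np.array([r.sasa for r in model[chain_id]])


def compute_rsa(structure: ChainStructure) -> RsaProfile:
    """Shrake-Rupley accessibility of the chain, free and complexed.

    The free context strips all partner chains before the calculation; for
    a monomer both contexts coincide. RSA% = 100 * ASA / maxASA(residue
    type), with the maximum-ASA reference recorded in the profile.
    """
    complexed_model = copy.deepcopy(structure.model)
    asa_complexed = _residue_sasa(complexed_model, structure.chain_id)
    if structure.is_multimer:
        free_model = Model(0)
        free_model.add(copy.deepcopy(structure.chain))
        asa_free = _residue_sasa(free_model, structure.chain_id)
    else:
        asa_free = asa_complexed.copy()
    max_asa = np.array(
        [MAX_ASA_TIEN_2013_THEORETICAL[r.one_letter] for r in structure.residues]
    )
    return RsaProfile(
        asa_free=asa_free,
        asa_complexed=asa_complexed,
        rsa_free=100.0 * asa_free / max_asa,
        rsa_complexed=100.0 * asa_complexed / max_asa,
    )


def rsa_by_query_position(
    rsa_values: np.ndarray, mapping: SeqStructMapping, query_length: int
) -> np.ndarray:
    """Scatter per-chain-residue RSA onto query positions; NaN where the
    query has no structural counterpart."""
    out = np.full(query_length, np.nan)
    for qpos, cidx in mapping.pairs:
        out[qpos - 1] = rsa_values[cidx]
    return out


def structure_aware_scores(
    landscape: MutationalLandscape,
    rsa_per_position: np.ndarray,
    ) -> np.ndarray:
    """RSA-modulated 19xL score matrix.

    score_rsa = score_evol * (1 - min(RSA, 100)/100); the multiplier lies in
    [0, 1], so modulation can only shrink a score towards zero. Positions
    with NaN RSA (unaligned) are NaN across all 19 cells.
    """
    rsa = np.asarray(rsa_per_position, dtype=float)
    if len(rsa) != landscape.length:
        raise StructureError("RSA vector length does not match the landscape")
    multiplier = 1.0 - np.clip(rsa, 0.0, 100.0) / 100.0
    return landscape.scores * multiplier[:, None]


def export_bfactor_pdb(
    structure: ChainStructure,
    values: np.ndarray,
    out_path: str | Path,
    fill: float = UNMAPPED_BFACTOR,
) -> None:
    """Write the chain with per-residue values in the B-factor column.

    One value per retained residue (NaN -> ``fill``, default -99.0), stamped
    on every atom of the residue so any molecular viewer can colour by it.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(structure.residues):
        raise StructureError("one value per retained residue is required")
    out_model = Model(0)
    out_model.add(copy.deepcopy(structure.chain))
    for residue, value in zip(out_model[structure.chain_id], values):
        v = fill if not np.isfinite(value) else float(value)
        for atom in residue.get_atoms():
            atom.set_bfactor(v)
    out_structure = Structure("proteocast")
    out_structure.add(out_model)
    io = PDBIO()
    io.set_structure(out_structure)
    io.save(str(out_path))
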