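"""Synthetic fixtures: MSAs with planted motifs, three-class mutational
landscapes with planted sensitivity segments, and toy PDB structures.

These generators make the whole toolkit testable offline. Each one returns
the generating truth (column profiles, true classes, true changepoints)
alongside the data so recovery tests can compare against it. They emulate
the statistical shape of real inputs — conserved motifs inside divergent,
gappy disordered background; a trimodal raw-score distribution; buried
interface residues in a dimer — not their biophysical detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, ONE_TO_THREE
from .errors import SyntheticSpecError
from .landscape import MutationalLandscape
from .msa import Msa


@dataclass
class LandscapeTruth:
    """Generating truth of a synthetic landscape, for recovery tests."""

    class_means: tuple[float, ...]
    class_sds: tuple[float, ...]
    class_weights: tuple[float, ...]
    true_class: np.ndarray  # (L, 20) component index, -1 at wild-type cells
    shifts: np.ndarray  # per-position segment-level mean shift
    changepoints: list[int]  # 1-based segment ends implied by the shifts
    seed: int = 0


def _check_spans(spans: list[tuple[int, int]], L: int, what: str) -> None:
    prev_end = 0
    for start, end in sorted(spans):
        if not (1 <= start <= end <= L):
            raise SyntheticSpecError(f"{what} ({start}, {end}) outside [1, {L}]")
        if start <= prev_end:
            raise SyntheticSpecError(f"overlapping {what}s at position {start}")
        prev_end = end


def generate_synthetic_msa(
    L: int = 120,
    n_sequences: int = 200,
    motif_spec: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    background_conservation: float = 0.25,
    background_gap_fraction: float = 0.3,
    motif_gap_fraction: float = 0.05,
) -> tuple[Msa, np.ndarray]:
    """MSA with conserved motifs embedded in divergent, gappy background.

    ``motif_spec`` lists (start, end, conservation) spans, 1-based closed,
    non-overlapping. Every column's letters are drawn iid from a profile in
    which the query letter has the requested conservation and the remainder
    is spread over five random alternatives; motif columns are almost
    ungapped, background columns heavily gapped, as in real IDR alignments.
    Returns the alignment and the (L, 21) generating profile over
    AA_ORDER + gap for oracle checks.
    """
    motif_spec = motif_spec or []
    _check_spans([(s, e) for s, e, _ in motif_spec], L, "motif")
    rng = np.random.default_rng(seed)
    query_idx = rng.integers(0, 20, size=L)
    conservation = np.full(L, background_conservation)
    gap_p = np.full(L, background_gap_fraction)
    for start, end, cons in motif_spec:
        conservation[start - 1 : end] = cons
        gap_p[start - 1 : end] = motif_gap_fraction

    profiles = np.zeros((L, 21))
    for j in range(L):
        aa_probs = np.zeros(20)
        aa_probs[query_idx[j]] = conservation[j]
        others = [k for k in range(20) if k != query_idx[j]]
        chosen = rng.choice(others, size=5, replace=False)
        aa_probs[chosen] = (1 - conservation[j]) * rng.dirichlet(np.ones(5))
        profiles[j, :20] = aa_probs * (1 - gap_p[j])
        profiles[j, 20] = gap_p[j]

    query = "".join(AA_ORDER[k] for k in query_idx)
    symbols = np.array(list(AA_ORDER) + ["-"])
    rows = [query]
    ids = ["query"]
    for s in range(1, n_sequences):
        draws = [
            symbols[rng.choice(21, p=profiles[j])] for j in range(L)
        ]
        rows.append("".join(draws))
        ids.append(f"seq{s}")
    msa = Msa(query_id="query", query_seq=query, ids=tuple(ids), rows=tuple(rows))
    return msa, profiles


def generate_synthetic_landscape(
    L: int = 300,
    class_means: tuple[float, float, float] = (-8.0, -4.0, 0.0),
    class_sds: tuple[float, float, float] = (0.5, 0.5, 0.5),
    class_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    segment_plan: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    query_seq: str | None = None,
) -> tuple[MutationalLandscape, LandscapeTruth]:
    """19xL landscape with trimodal scores and planted sensitivity segments.

    Every substitution cell draws a component from ``class_weights`` and a
    score from the matching Gaussian, plus a per-position mean shift taken
    from ``segment_plan`` — (start, end, shift) spans, 1-based closed, with
    shift 0 elsewhere. Negative shifts plant segments of elevated
    sensitivity. The truth record carries the component of every cell and
    the changepoints implied by the shift profile.
    """
    if not (
        len(class_means) == len(class_sds) == len(class_weights) == 3
    ):
        raise SyntheticSpecError("exactly three score classes are required")
    if list(class_means) != sorted(class_means):
        raise SyntheticSpecError("class means must be sorted ascending")
    segment_plan = segment_plan or []
    _check_spans([(s, e) for s, e, _ in segment_plan], L, "plan segment")
    rng = np.random.default_rng(seed)
    if query_seq is None:
        query_seq = "".join(AA_ORDER[k] for k in rng.integers(0, 20, size=L))
    elif len(query_seq) != L:
        raise SyntheticSpecError("query_seq length does not match L")

    shifts = np.zeros(L)
    for start, end, shift in segment_plan:
        shifts[start - 1 : end] = shift
    means = np.asarray(class_means)
    sds = np.asarray(class_sds)
    comp = rng.choice(3, size=(L, 20), p=np.asarray(class_weights))
    scores = rng.normal(means[comp] + shifts[:, None], sds[comp])
    true_class = comp.copy()
    for i, wt in enumerate(query_seq):
        scores[i, AA_INDEX[wt]] = np.nan
        true_class[i, AA_INDEX[wt]] = -1

    boundaries = np.flatnonzero(np.diff(shifts) != 0) + 1  # 1-based ends
    changepoints = boundaries.tolist() + [L]
    truth = LandscapeTruth(
        class_means=tuple(class_means),
        class_sds=tuple(class_sds),
        class_weights=tuple(class_weights),
        true_class=true_class,
        shifts=shifts,
        changepoints=changepoints,
        seed=seed,
    )
    return (
        MutationalLandscape(wild_type=query_seq, scores=scores, scorer="synthetic"),
        truth,
    )


def planted_profile(
    n: int,
    changepoints: list[int],
    segment_means: list[float],
    sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-constant signal plus iid Gaussian noise; ``changepoints``
    are 1-based segment ends whose final entry must be n."""
    if not changepoints or changepoints[-1] != n:
        raise SyntheticSpecError("last changepoint must equal n")
    if len(changepoints) != len(segment_means):
        raise SyntheticSpecError("one mean per segment is required")
    rng = np.random.default_rng(seed)
    mu = np.empty(n)
    start = 0
    for end, m in zip(changepoints, segment_means):
        mu[start:end] = m
        start = end
    return mu + rng.normal(0.0, sigma, size=n)


# --- toy structures ---------------------------------------------------------

_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)
_CA_RADIUS = 2.3


def _helix_atoms(i: int) -> list[tuple[str, str, tuple[float, float, float]]]:
    t = i * _HELIX_TURN
    z = i * _HELIX_RISE

    def ring(r, dt, dz):
        return (r * math.cos(t + dt), r * math.sin(t + dt), z + dz)

    return [
        ("N", "N", ring(1.6, -0.5, -0.9)),
        ("CA", "C", ring(_CA_RADIUS, 0.0, 0.0)),
        ("C", "C", ring(1.9, 0.45, 0.8)),
        ("O", "O", ring(2.4, 0.75, 1.3)),
        ("CB", "C", ring(3.6, 0.0, 0.4)),
    ]


def _extended_atoms(i: int) -> list[tuple[str, str, tuple[float, float, float]]]:
    x = 3.8 * i
    return [
        ("N", "N", (x - 1.3, 0.6, 0.0)),
        ("CA", "C", (x, 0.0, 0.0)),
        ("C", "C", (x + 1.3, -0.6, 0.0)),
        ("O", "O", (x + 1.5, -1.8, 0.2)),
        ("CB", "C", (x, 0.9, 1.3)),
    ]


def _atom_line(serial, name, resname, chain_id, resseq, xyz, bfactor, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain_id}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactor:6.2f}          {element:>2s}"
    )


def generate_toy_structure(
    seq: str,
    conformation: str = "helix",
    n_chains: int = 1,
    plddt: list[float] | np.ndarray | None = None,
    chain_offset: tuple[float, float, float] | None = None,
) -> str:
    """PDB text for an idealised backbone (N, CA, C, O, CB) of ``seq``.

    ``conformation`` is "helix" or "extended"; glycines get no CB. With
    n_chains=2 a translated copy (chain B) is placed close enough to bury
    interface atoms, giving rsa_free > rsa_complexed fixtures. ``plddt``,
    when given, is written per residue into the B-factor column of every
    chain.
    """
    if len(seq) > 50:
        raise SyntheticSpecError("toy structures are capped at 50 residues")
    if n_chains not in (1, 2):
        raise SyntheticSpecError("n_chains must be 1 or 2")
    bad = {c for c in seq if c not in ONE_TO_THREE}
    if bad:
        raise SyntheticSpecError(f"unsupported residue letters: {sorted(bad)}")
    if plddt is not None and len(plddt) != len(seq):
        raise SyntheticSpecError("one pLDDT value per residue is required")
    if conformation == "helix":
        builder, default_offset = _helix_atoms, (0.0, 7.0, 0.0)
    elif conformation == "extended":
        builder, default_offset = _extended_atoms, (0.0, 5.5, 0.0)
    else:
        raise SyntheticSpecError(f"unknown conformation {conformation!r}")
    offset = chain_offset if chain_offset is not None else default_offset

    lines = []
    serial = 1
    for c in range(n_chains):
        chain_id = "AB"[c]
        dx, dy, dz = (0.0, 0.0, 0.0) if c == 0 else offset
        for i, aa in enumerate(seq):
            resname = ONE_TO_THREE[aa]
            bf = float(plddt[i]) if plddt is not None else 0.0
            for name, element, (x, y, z) in builder(i):
                if name == "CB" and aa == "G":
                    continue
                lines.append(
                    _atom_line(
                        serial, name, resname, chain_id, i + 1,
                        (x + dx, y + dy, z + dz), bf, element,
                    )
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
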