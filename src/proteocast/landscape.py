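"""The 19×L mutational landscape and the per-residue sensitivity profile.

The landscape holds one raw evolutionary score per (position, substituting
amino acid): more negative = stronger predicted functional impact. Wild-type
cells are not variants and carry NaN so that they can never leak into the
mixture fit or the sensitivity profile.

Scores normally come from an external predictor (e.g. a GEMME run) ingested
via :func:`load_score_matrix`. For fully offline use, :func:`baseline_scores`
provides a deliberately simple column-independent log-odds scorer; it is
labelled ``baseline`` in run metadata and is not a substitute for a
tree-aware predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AA_ORDER, AA_SET
from .errors import ScoreMatrixError
from .msa import Msa


@dataclass
class MutationalLandscape:
    """Scores indexed by (position 0-based, amino acid in AA_ORDER)."""

    wild_type: str
    scores: np.ndarray  # (L, 20), NaN at wild-type and unscored cells
    scorer: str = "ingested"

    @property
    def length(self) -> int:
        return len(self.wild_type)

    def __post_init__(self) -> None:
        if self.scores.shape != (self.length, 20):
            raise ScoreMatrixError(
                f"score matrix shape {self.scores.shape} does not match "
                f"query length {self.length}"
            )
        for i, wt in enumerate(self.wild_type):
            if wt in AA_INDEX and np.isfinite(self.scores[i, AA_INDEX[wt]]):
                raise ScoreMatrixError(
                    f"wild-type cell ({i + 1}, {wt}) must be missing, not scored"
                )

    def finite_scores(self) -> np.ndarray:
        return self.scores[np.isfinite(self.scores)]

    def dispersion(self) -> np.ndarray:
        """Per-position standard deviation (population) of the available
        substitution scores; NaN where a position has no scores."""
        finite = np.isfinite(self.scores)
        n = finite.sum(axis=1)
        denom = np.maximum(n, 1)
        vals = np.where(finite, self.scores, 0.0)
        mean = vals.sum(axis=1) / denom
        var = (np.where(finite, (self.scores - mean[:, None]) ** 2, 0.0)).sum(
            axis=1
        ) / denom
        return np.where(n > 0, np.sqrt(var), np.nan)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form table with one row per substitution (19 per position)."""
        rows = []
        for i, wt in enumerate(self.wild_type):
            for a in AA_ORDER:
                if a == wt:
                    continue
                rows.append((i + 1, wt, a, self.scores[i, AA_INDEX[a]]))
        return pd.DataFrame(rows, columns=["position", "wt", "mut", "raw_score"])


@dataclass
class SensitivityProfile:
    """Per-residue mean of the substitution scores; the segmented signal."""

    values: np.ndarray  # length L
    n_scored: np.ndarray = field(default=None)  # substitutions averaged per position

    @property
    def n(self) -> int:
        return len(self.values)


def _empty_scores(L: int) -> np.ndarray:
    return np.full((L, 20), np.nan)


def _validate_query(query_seq: str) -> None:
    bad = {c for c in query_seq if c not in AA_SET and c != "X"}
    if bad:
        raise ScoreMatrixError(f"query contains invalid letters: {sorted(bad)}")


def load_score_matrix(path: str | Path, query_seq: str) -> MutationalLandscape:
    """Ingest an external 19×L score matrix from CSV.

    Two layouts are accepted:

    * long form with header ``position,wt,mut,score`` (one row per
      substitution, positions 1-based);
    * grid form with 20 rows — first column the substituting amino acid in
      alphabetical order, remaining columns positions ``1..L``.

    The wt column (long form) or the query letters (both forms) must match
    ``query_seq``; duplicate (position, mut) entries are an error.
    """
    _validate_query(query_seq)
    L = len(query_seq)
    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if {"position", "wt", "mut", "score"}.issubset(cols):
        df.columns = cols
        return _from_long(df, query_seq)
    # grid form: first column is the amino-acid letter
    first = df.columns[0]
    aas = [str(a).strip().upper() for a in df[first]]
    if sorted(aas) != sorted(AA_ORDER):
        raise ScoreMatrixError(
            "unrecognised score CSV: neither long form (position,wt,mut,score) "
            "nor a 20-row amino-acid grid"
        )
    grid = df.drop(columns=[first])
    if grid.shape[1] != L:
        raise ScoreMatrixError(
            f"grid has {grid.shape[1]} position columns, query length is {L}"
        )
    scores = _empty_scores(L)
    for row_idx, aa in enumerate(aas):
        vals = pd.to_numeric(grid.iloc[row_idx], errors="coerce")
        if grid.iloc[row_idx].notna().any() and vals.isna().all():
            raise ScoreMatrixError(f"non-numeric scores in grid row {aa}")
        scores[:, AA_INDEX[aa]] = vals.to_numpy(dtype=float)
    for i, wt in enumerate(query_seq):
        if wt in AA_INDEX:
            scores[i, AA_INDEX[wt]] = np.nan
    return MutationalLandscape(wild_type=query_seq, scores=scores)


def _from_long(df: pd.DataFrame, query_seq: str) -> MutationalLandscape:
    L = len(query_seq)
    scores = _empty_scores(L)
    seen: set[tuple[int, str]] = set()
    for rec in df.itertuples(index=False):
        try:
            pos = int(rec.position)
        except (TypeError, ValueError):
            raise ScoreMatrixError(f"non-integer position {rec.position!r}")
        wt, mut = str(rec.wt).strip().upper(), str(rec.mut).strip().upper()
        if not 1 <= pos <= L:
            raise ScoreMatrixError(f"position {pos} outside [1, {L}]")
        if wt != query_seq[pos - 1]:
            raise ScoreMatrixError(
                f"wt {wt!r} at position {pos} does not match query "
                f"{query_seq[pos - 1]!r}"
            )
        if mut not in AA_INDEX:
            raise ScoreMatrixError(f"unknown substituting amino acid {mut!r}")
        if mut == wt:
            raise ScoreMatrixError(f"({pos}, {mut}) scores the wild type")
        if (pos, mut) in seen:
            raise ScoreMatrixError(f"duplicate entry for ({pos}, {mut})")
        seen.add((pos, mut))
        try:
            scores[pos - 1, AA_INDEX[mut]] = float(rec.score)
        except (TypeError, ValueError):
            raise ScoreMatrixError(f"non-numeric score {rec.score!r} at ({pos}, {mut})")
    return MutationalLandscape(wild_type=query_seq, scores=scores)


def baseline_scores(msa: Msa, pseudocount: float = 1.0) -> MutationalLandscape:
    """Column-independent log-odds scores from MSA amino-acid counts.

    score(i, a) = log[(c_i(a) + q) / (c_i(wt_i) + q)] with q the pseudocount
    and c_i the non-gap count of amino acid a in column i. No phylogeny, no
    epistasis: this is an intentionally transparent baseline, recorded as
    ``scorer="baseline"`` so downstream outputs cannot be mistaken for a
    published predictor's.
    """
    if pseudocount <= 0:
        raise ScoreMatrixError("pseudocount must be positive")
    L = msa.length
    counts = np.zeros((L, 20))
    for row in msa.rows:
        for j, c in enumerate(row):
            if c in AA_INDEX:
                counts[j, AA_INDEX[c]] += 1
    scores = np.full((L, 20), np.nan)
    for i, wt in enumerate(msa.query_seq):
        wt_count = counts[i, AA_INDEX[wt]] if wt in AA_INDEX else 0.0
        scores[i] = np.log((counts[i] + pseudocount) / (wt_count + pseudocount))
        if wt in AA_INDEX:
            scores[i, AA_INDEX[wt]] = np.nan
    return MutationalLandscape(wild_type=msa.query_seq, scores=scores, scorer="baseline")


def sensitivity_profile(landscape: MutationalLandscape) -> SensitivityProfile:
    """Per-position arithmetic mean of the available substitution scores.

    With a complete landscape this is the mean of all 19 substitutions;
    positions with missing cells average the cells that are present (the
    count is kept in ``n_scored``), and a fully unscored position is NaN.
    """
    finite = np.isfinite(landscape.scores)
    sums = np.where(finite, landscape.scores, 0.0).sum(axis=1)
    n_scored = finite.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_scored > 0, sums / np.maximum(n_scored, 1), np.nan)
    return SensitivityProfile(values=values, n_scored=n_scored)
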