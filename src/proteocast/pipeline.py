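"""End-to-end orchestration: MSA -> landscape -> classification ->
segmentation -> structure modulation -> exports.

All outputs are deterministic given the configuration and seed; CSVs carry a
leading comment line stating the coordinate convention (1-based, closed
intervals). ``manifest.json`` lists every file a run writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import landscape as _landscape
from . import msa as _msa
from . import segment as _segment
from . import structure as _structure
from .errors import MutationFileError
from .alphabet import AA_INDEX

CSV_HEADER_COMMENT = "# proteocast output; positions are 1-based, intervals closed\n"
BED_HEADER_COMMENT = "# proteocast segments; BED coordinates are 0-based, half-open\n"


@dataclass
class RunConfig:
    msa_path: str
    dialect: str = "auto"
    scores_path: str | None = None
    structure_path: str | None = None
    chain_id: str = "A"
    alphafold_model: bool = False
    mutations_path: str | None = None
    pseudocount: float = 1.0
    alpha: float = 1.4
    w_high: float = 0.1
    plddt_cutoff: float = 70.0
    sigma2_override: float | None = None
    rsa_context: str = "auto"  # auto | complexed | free
    confidence: _classify.ConfidenceConfig = field(
        default_factory=_classify.ConfidenceConfig
    )
    seed: int = 0
    out_dir: str | None = None
    plots: bool = False
    bed: bool = False


@dataclass
class RunResult:
    variants: pd.DataFrame
    residues: pd.DataFrame
    segments: pd.DataFrame
    gmm: _classify.GmmFit
    segmentation: _segment.Segmentation
    landscape: _landscape.MutationalLandscape
    msa: _msa.Msa
    summary: dict
    manifest: list[str] = field(default_factory=list)
    structure: _structure.ChainStructure | None = None
    mapping: _structure.SeqStructMapping | None = None
    rsa: _structure.RsaProfile | None = None
    structure_aware: np.ndarray | None = None


def load_mutations(path: str | Path, query_seq: str) -> pd.DataFrame:
    """Validated annotated-mutation table with columns wt, position, mut,
    label. The wt letter must match the query; conflicting duplicate labels
    are an error, identical duplicates are collapsed."""
    df = pd.read_csv(path, comment="#")
    required = {"wt", "position", "mut", "label"}
    cols = {c.strip().lower() for c in df.columns}
    if not required.issubset(cols):
        raise MutationFileError(
            f"mutation CSV must have header wt,position,mut,label; got {sorted(cols)}"
        )
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        return df[["wt", "position", "mut", "label"]]
    df["wt"] = df["wt"].str.strip().str.upper()
    df["mut"] = df["mut"].str.strip().str.upper()
    df["position"] = df["position"].astype(int)
    for rec in df.itertuples(index=False):
        if not 1 <= rec.position <= len(query_seq):
            raise MutationFileError(f"position {rec.position} outside the query")
        if rec.wt != query_seq[rec.position - 1]:
            raise MutationFileError(
                f"wt {rec.wt!r} at position {rec.position} does not match "
                f"query {query_seq[rec.position - 1]!r}"
            )
        if rec.mut == rec.wt:
            raise MutationFileError(
                f"({rec.position}, {rec.mut}) is not a substitution"
            )
        if rec.mut not in AA_INDEX:
            raise MutationFileError(f"unknown amino acid {rec.mut!r}")
    df = df.drop_duplicates()
    dup = df.duplicated(subset=["position", "mut"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise MutationFileError(
            f"conflicting labels for ({first['position']}, {first['mut']})"
        )
    return df[["wt", "position", "mut", "label"]]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, comment: str = CSV_HEADER_COMMENT) -> None:
    with open(path, "w") as fh:
        fh.write(comment)
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> RunResult:
    warnings: list[str] = []

    msa = _msa.read_msa(config.msa_path, config.dialect)
    stats = _msa.column_stats_frame(msa)
    sims = np.array(
        [s.identity_to_query for s in _msa.similarity_to_query(msa)]
    )
    if msa.n_sequences < 30:
        warnings.append(f"shallow MSA: only {msa.n_sequences} sequences")

    if config.scores_path:
        land = _landscape.load_score_matrix(config.scores_path, msa.query_seq)
    else:
        land = _landscape.baseline_scores(msa, config.pseudocount)

    fit = _classify.fit_gmm3(land.finite_scores(), seed=config.seed)
    if fit.threshold_fallback:
        warnings.append(
            f"GMM threshold fallback (midpoint) used: {fit.threshold_fallback}"
        )
    if fit.init != "quantile":
        warnings.append(f"GMM quantile initialisation collapsed; used {fit.init}")

    variants = _classify.classify_variants(land, fit)
    residues = _classify.classify_residues(variants)
    confidence = _classify.residue_confidence(
        stats, land.dispersion(), config.confidence
    )
    residues = residues.merge(stats, on="position").merge(confidence, on="position")
    variants = variants.merge(
        confidence[["position", "confident"]], on="position", how="left"
    )

    if config.mutations_path:
        muts = load_mutations(config.mutations_path, msa.query_seq)
        variants = variants.merge(
            muts[["position", "mut", "label"]], on=["position", "mut"], how="left"
        )
        variants["label"] = variants["label"].fillna("")

    structure = mapping = rsa = None
    sa_scores = None
    plddt_q = None
    if config.structure_path:
        structure = _structure.read_chain(
            config.structure_path, config.chain_id, config.alphafold_model
        )
        mapping = _structure.align_query_to_chain(msa.query_seq, structure.sequence)
        if mapping.identity < 0.3:
            warnings.append(
                f"low sequence-structure identity ({mapping.identity:.2f})"
            )
        rsa = _structure.compute_rsa(structure)
        context = config.rsa_context
        if context == "auto":
            context = "complexed" if structure.is_multimer else "free"
        rsa_chain = rsa.rsa_complexed if context == "complexed" else rsa.rsa_free
        rsa_q = _structure.rsa_by_query_position(rsa_chain, mapping, msa.length)
        sa_scores = _structure.structure_aware_scores(land, rsa_q)
        plddt_chain = structure.plddt()
        if plddt_chain is not None:
            plddt_q = _structure.rsa_by_query_position(
                plddt_chain, mapping, msa.length
            )
        # per-query-position structure columns
        chain_resnum = np.full(msa.length, np.nan)
        for qpos, cidx in mapping.pairs:
            chain_resnum[qpos - 1] = structure.residues[cidx].resnum
        residues["chain_resnum"] = chain_resnum
        residues["rsa_free"] = _structure.rsa_by_query_position(
            rsa.rsa_free, mapping, msa.length
        )
        residues["rsa_complexed"] = _structure.rsa_by_query_position(
            rsa.rsa_complexed, mapping, msa.length
        )
        residues["plddt"] = (
            plddt_q if plddt_q is not None else np.full(msa.length, np.nan)
        )
        residues["aligned"] = np.isfinite(chain_resnum)
        sa_long = []
        for rec in variants.itertuples(index=False):
            sa_long.append(sa_scores[rec.position - 1, AA_INDEX[rec.mut]])
        variants["structure_aware_score"] = sa_long
        unaligned = mapping.unaligned_query_positions
        variants["aligned"] = ~variants["position"].isin(unaligned)

    profile = _landscape.sensitivity_profile(land)
    y = profile.values.copy()
    if not np.all(np.isfinite(y)):
        fill = float(np.nanmean(y))
        n_filled = int((~np.isfinite(y)).sum())
        warnings.append(
            f"{n_filled} unscored positions imputed with the profile mean "
            "before segmentation"
        )
        y = np.where(np.isfinite(y), y, fill)
    seg_config = _segment.SegmentationConfig(
        alpha=config.alpha,
        w_high=config.w_high,
        plddt_cutoff=config.plddt_cutoff,
        sigma2_override=config.sigma2_override,
    )
    seg = _segment.segment_profile(
        _landscape.SensitivityProfile(values=y, n_scored=profile.n_scored),
        plddt_q,
        seg_config,
    )
    highlighted = seg.in_idr & (seg.segment_scores >= 1)
    segments = pd.DataFrame(
        {
            "segment_id": np.arange(1, seg.n_segments + 1),
            "start": seg.starts,
            "end": seg.ends,
            "mean": seg.segment_means,
            "score": seg.segment_scores,
            "in_idr": seg.in_idr,
            "highlighted": highlighted,
        }
    )
    residues.insert(1, "wt", [c for c in msa.query_seq])
    residues["sensitivity"] = profile.values
    seg_of_pos = np.empty(msa.length, dtype=int)
    for j, (s, e) in enumerate(zip(seg.starts, seg.ends)):
        seg_of_pos[s - 1 : e] = j + 1
    residues["segment_id"] = seg_of_pos

    summary = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "scorer": land.scorer,
        "query_id": msa.query_id,
        "query_length": msa.length,
        "msa_depth": msa.n_sequences,
        "identity_to_query": {
            "median": float(np.median(sims)),
            "q10": float(np.quantile(sims, 0.1)),
            "q90": float(np.quantile(sims, 0.9)),
        },
        "gmm": fit.to_dict(),
        "fraction_confident": float(residues["confident"].mean()),
        "sigma2": seg.variance.sigma2,
        "sigma2_method": seg.variance.method,
        "penalty": seg.penalty,
        "n_segments": seg.n_segments,
        "n_highlighted_segments": int(highlighted.sum()),
        "structure": None,
        "warnings": warnings,
    }
    if structure is not None:
        summary["structure"] = {
            "chain_id": structure.chain_id,
            "source": structure.source,
            "n_chains": structure.n_chains,
            "n_residues": len(structure.residues),
            "alignment_score": mapping.alignment_score,
            "alignment_identity": mapping.identity,
            "n_unaligned_query_positions": len(mapping.unaligned_query_positions),
            "rsa_context": context,
            "max_asa_table": rsa.max_asa_table,
        }

    result = RunResult(
        variants=variants,
        residues=residues,
        segments=segments,
        gmm=fit,
        segmentation=seg,
        landscape=land,
        msa=msa,
        summary=summary,
        structure=structure,
        mapping=mapping,
        rsa=rsa,
        structure_aware=sa_scores,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _segment_values_per_chain_residue(
    result: RunResult, per_position: np.ndarray
) -> np.ndarray:
    """Scatter query-position values onto the chain's retained residues."""
    values = np.full(len(result.structure.residues), np.nan)
    for qpos, cidx in result.mapping.pairs:
        values[cidx] = per_position[qpos - 1]
    return values


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = ["variants.csv", "residues.csv", "segments.csv", "gmm.json",
                "run_summary.json", "manifest.json"]
    _write_csv(result.variants, out / "variants.csv")
    _write_csv(result.residues, out / "residues.csv")
    _write_csv(result.segments, out / "segments.csv")
    (out / "gmm.json").write_text(json.dumps(result.gmm.to_dict(), indent=2) + "\n")
    (out / "run_summary.json").write_text(
        json.dumps(result.summary, indent=2) + "\n"
    )
    if config.bed:
        manifest.append("segments.bed")
        seg = result.segments
        bed = pd.DataFrame(
            {
                "chrom": "query",
                "start": seg["start"] - 1,  # 0-based, half-open
                "end": seg["end"],
                "name": "segment_" + seg["segment_id"].astype(str),
                "score": seg["score"] * 500,
            }
        )
        with open(out / "segments.bed", "w") as fh:
            fh.write(BED_HEADER_COMMENT)
            bed.to_csv(fh, sep="\t", index=False, header=False, lineterminator="\n")
    if result.structure is not None:
        sens = _segment_values_per_chain_residue(
            result, result.residues["sensitivity"].to_numpy()
        )
        class_code = _segment_values_per_chain_residue(
            result,
            np.where(result.residues["residue_class"].eq("sensitive"), 1.0, 0.0),
        )
        with np.errstate(invalid="ignore"):
            sa_sens = np.where(
                np.isfinite(result.structure_aware).any(axis=1),
                np.nansum(
                    np.where(
                        np.isfinite(result.structure_aware),
                        result.structure_aware,
                        0.0,
                    ),
                    axis=1,
                )
                / np.maximum(np.isfinite(result.structure_aware).sum(axis=1), 1),
                np.nan,
            )
        sa_per_chain = _segment_values_per_chain_residue(result, sa_sens)
        for fname, values in [
            ("sensitivity.pdb", sens),
            ("class.pdb", class_code),
            ("structure_aware.pdb", sa_per_chain),
        ]:
            _structure.export_bfactor_pdb(result.structure, values, out / fname)
            manifest.append(fname)
    if config.plots:
        manifest.extend(_write_plots(result, out))
    result.manifest = sorted(manifest)
    (out / "manifest.json").write_text(
        json.dumps({"files": result.manifest}, indent=2) + "\n"
    )


def _write_plots(result: RunResult, out: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # landscape heatmap
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(
        result.landscape.scores.T, aspect="auto", cmap="viridis",
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="raw evolutionary score")
    ax.set_xlabel("position")
    ax.set_ylabel("substituting amino acid")
    fig.savefig(out / "landscape.png", dpi=120)
    plt.close(fig)
    written.append("landscape.png")
    # sensitivity profile with segments
    fig, ax = plt.subplots(figsize=(10, 3))
    y = result.residues["sensitivity"].to_numpy()
    ax.plot(np.arange(1, len(y) + 1), y, lw=0.8, color="0.4")
    colors = {0: "0.6", 1: "tab:red", 2: "purple"}
    seg = result.segmentation
    for s, e, m, sc in zip(
        seg.starts, seg.ends, seg.segment_means, seg.segment_scores
    ):
        ax.hlines(m, s, e, colors=colors[int(sc)], lw=2.5)
    ax.set_xlabel("position")
    ax.set_ylabel("mean substitution score")
    fig.savefig(out / "profile.png", dpi=120)
    plt.close(fig)
    written.append("profile.png")
    # MSA similarity summary
    fig, ax = plt.subplots(figsize=(6, 3))
    sims = [s.identity_to_query for s in _msa.similarity_to_query(result.msa)]
    ax.hist(sims, bins=30, color="tab:blue")
    ax.set_xlabel("identity to query")
    ax.set_ylabel("sequences")
    fig.savefig(out / "msa_similarity.png", dpi=120)
    plt.close(fig)
    written.append("msa_similarity.png")
    return written
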