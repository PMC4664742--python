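"""End-to-end orchestration: dedup -> search -> extract -> filter ->
fold -> validate -> (targets) -> (phylogeny).

Every stage writes its table under the output directory and the run
ends with a machine-readable ``summary.json`` of per-stage counts and
the file manifest.  All outputs are formatted deterministically: two
runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import folding, hairpin, homology, phylo, precursor, seqio, targets

logger = logging.getLogger("estmir")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and switches of one pipeline run."""

    mirna_fasta: str
    est_fasta: str
    outdir: str
    folds_file: str | None = None
    exclusion_list: str | None = None
    transcripts_fasta: str | None = None
    flank: int = precursor.DEFAULT_FLANK
    orf_screen: bool = False
    min_orf_aa: int = 80
    run_phylo: bool = False
    phylo_on: str = "mature"  # mature | precursor
    search: homology.SearchParams = field(default_factory=homology.SearchParams)
    criteria: hairpin.CriteriaConfig = field(default_factory=hairpin.CriteriaConfig)
    target_params: targets.TargetParams = field(default_factory=targets.TargetParams)
    log_level: str = "INFO"


def table1_row(
    mirna_id: str,
    mature_sequence: str,
    star_sequence: str,
    precursor_len: int,
    gc_pct: float,
    mfe: float,
) -> dict:
    """One row of the passed-candidate report.

    Columns mirror the conventional plant pre-miRNA summary table:
    mature and star sequences with their lengths LM and LS, precursor
    length LP, G+C%, MFE and the MFEI derived from them.
    """
    return {
        "mirna_id": mirna_id,
        "mature_sequence": mature_sequence,
        "star_sequence": star_sequence,
        "LM": len(mature_sequence),
        "LS": len(star_sequence),
        "LP": precursor_len,
        "gc_pct": gc_pct,
        "mfe": mfe,
        "mfei": folding.compute_mfei(mfe, precursor_len, gc_pct),
    }


_EVAL_HEADER = (
    "candidate_id\tmirna_id\test_id\tstrand\tarm\tLM\tLS\tLP\tgc_pct\tau_pct\t"
    "mfe\tamfe\tmfei\tstar_mismatches\tverdict\tfailure_reasons\n"
)


def _write_evaluations(
    rows: list[tuple[precursor.PrecursorCandidate, hairpin.HairpinEvaluation]],
    path: Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(_EVAL_HEADER)
        for cand, ev in rows:
            fh.write(
                f"{cand.candidate_id}\t{cand.mirna_id}\t{cand.est_id}\t"
                f"{cand.strand}\t{ev.arm}\t{cand.mature_len}\t{ev.star_len}\t"
                f"{cand.precursor_len}\t{ev.stats.gc_pct:.2f}\t"
                f"{ev.stats.au_pct:.2f}\t{ev.mfe:.2f}\t{ev.stats.amfe:.4f}\t"
                f"{ev.stats.mfei:.8f}\t{ev.star_mismatches}\t"
                f"{'pass' if ev.passed else 'fail'}\t"
                f"{';'.join(ev.failure_reasons)}\n"
            )


def _write_report(
    rows: list[tuple[precursor.PrecursorCandidate, hairpin.HairpinEvaluation]],
    path: Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "candidate_id\tmirna_id\tmature_sequence\tstar_sequence\t"
            "LM\tLS\tLP\tgc_pct\tmfe\tmfei\n"
        )
        for cand, ev in rows:
            if not ev.passed:
                continue
            row = table1_row(
                cand.mirna_id,
                cand.mature_sequence,
                ev.star_sequence,
                cand.precursor_len,
                ev.stats.gc_pct,
                ev.mfe,
            )
            fh.write(
                f"{cand.candidate_id}\t{row['mirna_id']}\t"
                f"{row['mature_sequence']}\t{row['star_sequence']}\t"
                f"{row['LM']}\t{row['LS']}\t{row['LP']}\t"
                f"{row['gc_pct']:.2f}\t{row['mfe']:.2f}\t{row['mfei']:.8f}\n"
            )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full discovery pipeline; returns the summary dict.

    Exit state: the summary is written even when no candidate passes;
    stage errors propagate with the stage named in the log.
    """
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def out(name: str) -> Path:
        # manifest keeps names relative to outdir so runs into different
        # directories stay byte-identical
        manifest[name] = name
        return outdir / name

    logger.info("stage dedup: reading reference miRNAs from %s", cfg.mirna_fasta)
    mirnas_raw = seqio.read_fasta(cfg.mirna_fasta, alphabet="rna")
    mirnas = seqio.dedup_identical(mirnas_raw)
    seqio.write_fasta(mirnas, out("mirnas_dedup.fasta"))

    ests = seqio.read_fasta(cfg.est_fasta, alphabet="dna")
    est_by_id = {e.id: e for e in ests}

    logger.info(
        "stage search: %d miRNAs vs %d ESTs", len(mirnas), len(ests)
    )
    hits = homology.find_hits(mirnas, ests, cfg.search)
    homology.write_hits_tsv(hits, out("hits.tsv"))

    logger.info("stage extract: %d hits", len(hits))
    candidates = [
        precursor.extract_precursor(est_by_id[h.est_id], h, cfg.flank) for h in hits
    ]
    excluded = (
        seqio.read_exclusion_list(cfg.exclusion_list)
        if cfg.exclusion_list
        else set()
    )
    candidates = precursor.apply_coding_filter(
        candidates, excluded, cfg.orf_screen, cfg.min_orf_aa
    )
    seqio.write_fasta(
        precursor.candidates_to_records(candidates), out("candidates.fasta")
    )

    if cfg.folds_file:
        logger.info("stage fold: replaying precomputed folds from %s", cfg.folds_file)
        backend: folding.FoldingBackend = folding.PrecomputedFolds(cfg.folds_file)
    else:
        logger.info("stage fold: folding %d candidates with ViennaRNA", len(candidates))
        backend = folding.ViennaBackend()
    folds = {c.candidate_id: folding.fold(c.sequence, backend) for c in candidates}
    folding.write_folds(folds, out("folds.txt"))

    logger.info("stage validate: evaluating %d candidates", len(candidates))
    evaluations = [
        (c, hairpin.evaluate(c, folds[c.candidate_id], cfg.criteria))
        for c in candidates
    ]
    _write_evaluations(evaluations, out("evaluations.tsv"))
    _write_report(evaluations, out("report.tsv"))
    passed = [(c, ev) for c, ev in evaluations if ev.passed]

    n_target_hits = 0
    if cfg.transcripts_fasta and passed:
        logger.info("stage targets: scanning %s", cfg.transcripts_fasta)
        transcripts = seqio.read_fasta(cfg.transcripts_fasta, alphabet="dna")
        seen: set[str] = set()
        queries = []
        for cand, _ in passed:
            if cand.candidate_id not in seen:
                seen.add(cand.candidate_id)
                queries.append(
                    seqio.SequenceRecord(
                        id=cand.candidate_id, sequence=cand.mature_sequence
                    )
                )
        t_hits = targets.scan_transcripts(queries, transcripts, cfg.target_params)
        targets.write_targets_tsv(t_hits, out("targets.tsv"))
        targets.write_edge_table(t_hits, out("edges.tsv"))
        n_target_hits = len(t_hits)

    if cfg.run_phylo and len(passed) >= 3:
        logger.info("stage phylo: %d passed candidates", len(passed))
        seqs = [
            seqio.SequenceRecord(
                id=cand.candidate_id,
                sequence=(
                    cand.mature_sequence
                    if cfg.phylo_on == "mature"
                    else cand.sequence
                ),
            )
            for cand, _ in passed
        ]
        dm = phylo.distance_matrix(seqs)
        phylo.write_phylip(dm, out("distances.phy"))
        phylo.write_newick(phylo.neighbor_joining(dm), out("tree.nwk"))

    summary = {
        "counts": {
            "mirnas_input": len(mirnas_raw),
            "mirnas_dedup": len(mirnas),
            "ests": len(ests),
            "hits": len(hits),
            "candidates": len(candidates),
            "folded": len(folds),
            "passed": len(passed),
            "target_hits": n_target_hits,
        },
        "files": dict(sorted(manifest.items())),
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done: %s", summary["counts"])
    return summary
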