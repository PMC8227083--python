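"""End-to-end allergenicity assessment workflow.

For each query protein the pipeline runs, in order: dual-mode homology
screening against the allergen database; multiple alignment, conservation
annotation and a neighbor-joining tree over queries + allergens; the
propensity-panel consensus epitope prediction; shared-motif analysis of the
predicted regions against the validated peach epitopes; and a PD-index scan
of every predicted epitope peptide against the allergen database.  Each
stage writes its own TSV/FASTA/Newick/JSON artifact, and a summary JSON
flags, per query:

* ``homology`` — any full-length identity above the structural-similarity
  remark threshold (70%) or any 80-aa-window identity at or above the
  Codex screening threshold (35%);
* ``validated_motifs`` — shared motifs with the validated peach epitopes;
* ``pd_matches`` — epitope peptides matching an allergen window under the
  PD threshold (default < 4).

Outputs are deterministic for a fixed config and seed (rows are sorted,
JSON keys are sorted, no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import conservation, epitopes, homology, overlap, pd_index, phylo
from .msa import progressive_msa, write_aligned_fasta
from .seq_io import read_fasta

logger = logging.getLogger("ltp_epimap")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    query_fasta: str
    allergen_fasta: str
    out_dir: str
    validated_epitopes: str | None = None  # None -> packaged peach fixture
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    full_length_identity_flag: float = 70.0  # structural-similarity remark
    window_identity_flag: float = 35.0  # Codex 80-aa screening criterion
    window: int = 80
    scales: tuple[str, ...] = epitopes.DEFAULT_SCALES
    scale_window: int = 7
    min_votes: int | None = None
    min_region_length: int = 6
    min_motif_length: int = 4
    pd_threshold: float = 4.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.full_length_identity_flag <= 100:
            raise ValueError("full_length_identity_flag must be a percentage")
        if not 0 <= self.window_identity_flag <= 100:
            raise ValueError("window_identity_flag must be a percentage")
        if self.pd_threshold < 0:
            raise ValueError("pd_threshold must be >= 0")
        if self.min_motif_length < 1 or self.min_region_length < 1:
            raise ValueError("minimum lengths must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["scales"] = list(data["scales"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the summary dict.

    Any stage failure raises :class:`StageError`; artifacts of completed
    stages are retained and ``manifest.json`` marks the run incomplete.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = homology.AlignmentParams(
        matrix=config.matrix, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    manifest: dict = {"stages": [], "complete": False, "config": dataclasses.asdict(config)}
    manifest["config"]["scales"] = list(config.scales)

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        stage = "load_inputs"
        queries = read_fasta(config.query_fasta)
        allergens = read_fasta(config.allergen_fasta)
        if config.validated_epitopes:
            validated = epitopes.load_reported_epitopes(config.validated_epitopes)
        else:
            validated = epitopes.load_reported_epitopes("validated")
        logger.info("loaded %d queries, %d allergens", len(queries), len(allergens))
        finish_stage(stage)

        stage = "homology_screen"
        all_hits: list[homology.AlignmentHit] = []
        for query in queries:
            all_hits.extend(homology.full_length_screen(query, allergens, params))
            all_hits.extend(
                homology.sliding_window_screen(query, allergens, config.window, 1, params)
            )
        all_hits.sort(key=lambda h: (h.query_id, h.mode.value, -h.identity_pct, h.subject_id))
        homology.write_hits(all_hits, out / "homology_hits.tsv")
        finish_stage(stage)

        stage = "msa_conservation_phylo"
        everything = list(queries) + [a for a in allergens if a.id not in {q.id for q in queries}]
        tree_newick = None
        if len(everything) >= 2:
            msa = progressive_msa(everything, params)
            write_aligned_fasta(msa, out / "alignment.afa")
            profile = conservation.conservation_profile(msa, everything[0].id)
            profile.write(out / "conservation.tsv")
            if len(everything) >= 3:
                tree = phylo.nj_tree(conservation.distance_matrix(msa), msa.ids)
                tree.write(out / "tree.nwk")
                tree_newick = tree.newick()
        finish_stage(stage)

        stage = "epitope_consensus"
        regions: list[epitopes.EpitopeRegion] = []
        for query in queries:
            profiles = epitopes.panel_profiles(query.residues, config.scales, config.scale_window)
            regions.extend(
                epitopes.consensus_regions(
                    query.residues,
                    profiles,
                    parent_id=query.id,
                    min_votes=config.min_votes,
                    min_region_length=config.min_region_length,
                )
            )
        epitopes.write_regions(regions, out / "epitope_regions.tsv")
        finish_stage(stage)

        stage = "epitope_overlap"
        overlap_report: dict[str, list[dict]] = {}
        for query in queries:
            mine = [r for r in regions if r.parent_id == query.id]
            checks = overlap.validated_epitope_check(mine, validated, config.min_motif_length)
            overlap_report[query.id] = [
                {
                    "validated": f"{c.validated.parent_id}:{c.validated.start}-{c.validated.end}",
                    "overlaps": c.overlaps,
                    "motifs": [m.motif for m in c.motifs],
                }
                for c in checks
            ]
        with open(out / "validated_overlap.json", "w", encoding="utf-8") as fh:
            json.dump(overlap_report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        finish_stage(stage)

        stage = "pd_scan"
        pd_rows = []
        for region in regions:
            for match in pd_index.db_scan(region.sequence, allergens, config.pd_threshold):
                pd_rows.append(
                    {
                        "query_id": region.parent_id,
                        "epitope": f"{region.start}-{region.end}",
                        "peptide": match.query,
                        "subject_id": match.subject_id,
                        "offset": match.offset,
                        "subject_peptide": match.subject_peptide,
                        "pd": round(match.pd, 4),
                    }
                )
        pd_rows.sort(key=lambda r: (r["query_id"], r["epitope"], r["pd"], r["subject_id"]))
        pd.DataFrame(
            pd_rows,
            columns=[
                "query_id",
                "epitope",
                "peptide",
                "subject_id",
                "offset",
                "subject_peptide",
                "pd",
            ],
        ).to_csv(out / "pd_matches.tsv", sep="\t", index=False)
        finish_stage(stage)

        stage = "summary"
        summary: dict = {"queries": {}, "tree": tree_newick}
        for query in queries:
            flhits = [
                h
                for h in all_hits
                if h.query_id == query.id and h.mode is homology.SearchMode.FULL_LENGTH
            ]
            winhits = [
                h
                for h in all_hits
                if h.query_id == query.id and h.mode is homology.SearchMode.WINDOW80
            ]
            motifs = sorted(
                {m for entry in overlap_report[query.id] for m in entry["motifs"]}
            )
            matches = [r for r in pd_rows if r["query_id"] == query.id]
            summary["queries"][query.id] = {
                "homology_flag": any(
                    h.identity_pct > config.full_length_identity_flag for h in flhits
                )
                or any(h.identity_pct >= config.window_identity_flag for h in winhits),
                "max_full_length_identity": max((h.identity_pct for h in flhits), default=None),
                "max_window_identity": max((h.identity_pct for h in winhits), default=None),
                "validated_motifs": motifs,
                "validated_motif_flag": bool(motifs),
                "n_pd_matches": len(matches),
                "pd_match_flag": bool(matches),
                "n_epitope_regions": len([r for r in regions if r.parent_id == query.id]),
            }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["complete"] = True
        finish_stage(stage)
        return summary
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise StageError(stage, exc) from exc
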