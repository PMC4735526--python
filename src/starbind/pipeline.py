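"""End-to-end CLIP analysis: tags + control -> enrichment -> logo -> spacing -> sites.

A single flat config drives the stages in order; every stage writes a TSV
under the output directory, and a machine-readable JSON report records the
summary statistics together with the full configuration (all defaults
serialized) for provenance.  Identical config + seed produces byte-identical
TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from starbind.bipartite import find_bipartite_sites, spacing_distribution
from starbind.kmers import RNA_BASES, build_logo_counts, enrich_kmers, select_top_kmers
from starbind.sequences import read_fasta

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_clip_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat key/value configuration for :func:`run_clip_analysis`.

    Defaults are the study parameters: 6-mers, raw p < 0.05, top 15 motifs,
    bipartite separation window 16..30 intervening nt.
    """

    tags: str = ""
    control: str = ""
    out_dir: str = "clip_analysis"
    k: int = 6
    alpha: float = 0.05
    top_n: int = 15
    flank: int = 5
    min_separation: int = 16
    max_separation: int = 30
    spacing_max_distance: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Paths of stage outputs plus summary statistics and provenance."""

    config: dict
    outputs: dict[str, str]
    summary: dict
    version: str = ""
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_clip_analysis(config: PipelineConfig) -> AnalysisReport:
    """Run the full CLIP tag analysis described by ``config``.

    Stages: ingest -> k-mer enrichment -> top-motif selection -> logo counts
    -> spacing distributions (tags vs control) -> bipartite site calls.
    Any stage error aborts with the stage name; outputs already written are
    preserved.

    All coordinates in the output TSVs are 0-based, half-open.
    """
    out = Path(config.out_dir)
    stage = "ingest"
    try:
        for label, path in (("tags", config.tags), ("control", config.control)):
            if not path or not Path(path).is_file():
                raise PipelineError(f"{label} file not found: {path!r}")
        out.mkdir(parents=True, exist_ok=True)
        tags = read_fasta(config.tags, name="tags")
        control = read_fasta(config.control, name="control")
        if len(tags) == 0:
            raise PipelineError(f"tags file {config.tags!r} contains no sequences")
        if len(control) == 0:
            raise PipelineError(f"control file {config.control!r} contains no sequences")
        logger.info("ingested %d tags, %d control sequences (seed=%d)",
                    len(tags), len(control), config.seed)

        outputs: dict[str, str] = {}

        stage = _stage("kmer_enrichment")
        results = enrich_kmers(tags, control, k=config.k, alpha=config.alpha)
        enrich_df = pd.DataFrame(
            [
                dict(kmer=r.kmer, obs_count=r.obs_count, obs_total=r.obs_total,
                     bg_count=r.bg_count, bg_total=r.bg_total, ratio=r.ratio,
                     chi2=r.chi2, p_value=r.p_value)
                for r in results
            ]
        )
        _write_tsv(enrich_df, out / "kmer_enrichment.tsv")
        outputs["kmer_enrichment"] = str(out / "kmer_enrichment.tsv")

        stage = _stage("top_kmers")
        top = select_top_kmers(results, n=config.top_n, alpha=config.alpha)
        _write_tsv(
            enrich_df[enrich_df.kmer.isin([r.kmer for r in top])],
            out / "top_kmers.tsv",
        )
        outputs["top_kmers"] = str(out / "top_kmers.tsv")

        stage = _stage("logo_counts")
        if top:
            logo = build_logo_counts(tags, top, flank=config.flank)
            logo_df = pd.DataFrame(
                logo.to_array(), index=list(RNA_BASES), columns=logo.positions
            )
            logo_df.insert(0, "base", logo_df.index)
            logo_df.to_csv(out / "logo_counts.tsv", sep="\t", index=False)
            n_logo = logo.n_sequences
        else:
            logger.warning("no significant k-mers; skipping logo counts")
            n_logo = 0
        outputs["logo_counts"] = str(out / "logo_counts.tsv")

        stage = _stage("spacing_distribution")
        d_tags = spacing_distribution(tags, max_distance=config.spacing_max_distance)
        d_ctrl = spacing_distribution(control, max_distance=config.spacing_max_distance)
        spacing_df = pd.DataFrame(
            dict(
                distance=d_tags.distances,
                clip_normalized=d_tags.normalized_count,
                control_normalized=d_ctrl.normalized_count,
            )
        )
        _write_tsv(spacing_df, out / "spacing.tsv")
        outputs["spacing"] = str(out / "spacing.tsv")

        stage = _stage("bipartite_sites")
        rows = []
        n_tags_with_site = 0
        for seq in tags:
            sites = find_bipartite_sites(
                seq, config.min_separation, config.max_separation
            )
            if sites:
                n_tags_with_site += 1
            for s in sites:
                rows.append(
                    dict(seq_id=seq.id, up_start=s.upstream.start,
                         down_start=s.downstream.start, separation=s.separation)
                )
        _write_tsv(
            pd.DataFrame(rows, columns=["seq_id", "up_start", "down_start", "separation"]),
            out / "bipartite_sites.tsv",
        )
        outputs["bipartite_sites"] = str(out / "bipartite_sites.tsv")

        stage = _stage("report")
        n_significant = sum(1 for r in results if r.p_value < config.alpha and r.ratio > 1)
        summary = dict(
            n_tags=len(tags),
            n_control=len(control),
            n_significant_kmers=n_significant,
            top_kmers=[r.kmer for r in top],
            n_tags_in_logo=n_logo,
            fraction_tags_with_bipartite_site=n_tags_with_site / len(tags),
            fraction_control_with_bipartite_site=None,
        )
        # control-side site fraction, for the enrichment comparison
        n_ctrl_with_site = sum(
            1 for seq in control
            if find_bipartite_sites(seq, config.min_separation, config.max_separation)
        )
        summary["fraction_control_with_bipartite_site"] = n_ctrl_with_site / len(control)

        from starbind import __version__

        report = AnalysisReport(
            config=dataclasses.asdict(config), outputs=outputs, summary=summary,
            version=__version__,
        )
        report.to_json(out / "report.json")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
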