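"""End-to-end orchestration: screen → annotate → cluster → profiles.

One :class:`RunConfig` carries every tunable of every stage, so a run is
reproducible from its saved config alone; all randomness in this package
lives in the synthetic generators, behind explicit seeds. Outputs are
fixed-schema TSVs plus a machine-readable manifest (config echo, input
checksums, package version) and a human-readable funnel summary.

Reported coordinates in output tables are 1-based inclusive (matching
the "position 105" convention of the annotation frame); internal
coordinates are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .abundance import CoverageTable, copy_number_profile, relative_abundance, transcript_summary
from .align import AlignParams
from .cluster import greedy_cluster
from .hydropathy import TopologyParams
from .motifs import MISSING_CHAR, UnalignableError, extract_motif
from .records import ProteinRecord, read_fasta, read_tsv, write_tsv
from .reference import load_reference
from .screen import read_hmm_hits, screen_opsin

logger = logging.getLogger("rhodosurvey")

SCHEMA_VERSION = "1"

#: versioned column sets of every output table
SCHEMAS = {
    "screen_results": [
        "record_id", "passed", "tm_count", "retinal_lysine_position", "fail_reasons",
    ],
    "motif_calls": [
        "record_id", "residue_97", "residue_101", "residue_105", "residue_108",
        "pump_motif", "combined_label", "pump_class", "tuning_class",
        "complete", "alignment_identity", "status",
    ],
    "clusters": ["representative_id", "member_id", "identity"],
    "abundance": [
        "sample_id", "depth_m", "category_type", "category",
        "copies_per_genome", "fraction",
    ],
    "expression": [
        "sample_id", "depth_m", "rhodopsin_reads", "total_nonrrna_reads",
        "fraction_percent",
    ],
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name (and record, if known)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    fasta: str = ""
    outdir: str = "rhodosurvey_run"
    hmm_hits: Optional[str] = None
    coverage: Optional[str] = None
    metadata: Optional[str] = None
    transcripts: Optional[str] = None
    # opsin screen
    window: int = 11
    threshold: float = 0.8
    min_tm_length: int = 10
    merge_gap: int = 3
    tm7_tolerance: int = 2
    max_x_fraction: float = 0.2
    evalue_max: float = 1e-5
    # alignment / annotation
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_identity: float = 0.25
    # dereplication
    cluster_threshold: float = 0.95
    cluster_level: str = "amino_acid"
    identity_denominator: str = "shorter"
    # abundance
    uscg_statistic: str = "mean"
    log_level: str = "INFO"

    @property
    def topology_params(self) -> TopologyParams:
        return TopologyParams(
            window=self.window, threshold=self.threshold,
            min_tm_length=self.min_tm_length, merge_gap=self.merge_gap,
        )

    @property
    def align_params(self) -> AlignParams:
        return AlignParams(
            matrix=self.matrix, gap_open=self.gap_open, gap_extend=self.gap_extend,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage; a
    ``RUN_INCOMPLETE`` marker is left in the output directory so partial
    outputs are recognisable.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "RUN_INCOMPLETE"
    marker.write_text("run in progress\n")

    inputs = {
        k: getattr(config, k)
        for k in ("fasta", "hmm_hits", "coverage", "metadata", "transcripts")
        if getattr(config, k)
    }
    for key, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"{key} file not found: {path}")

    try:
        reference = load_reference(topology_params=config.topology_params)

        # --- screen --------------------------------------------------------
        stage = "screen"
        try:
            records = read_fasta(config.fasta)
        except ValueError as exc:
            raise PipelineError("inputs", str(exc)) from exc
        if config.hmm_hits:
            candidates = read_hmm_hits(config.hmm_hits, evalue_max=config.evalue_max)
            records = [r for r in records if r.id in candidates]
            logger.info("%d candidates after HMM-hit restriction", len(records))
        results = []
        for rec in records:
            try:
                results.append(
                    screen_opsin(
                        rec, reference, config.topology_params, config.align_params,
                        tm7_tolerance=config.tm7_tolerance,
                        max_x_fraction=config.max_x_fraction,
                    )
                )
            except Exception as exc:
                raise PipelineError(stage, f"record {rec.id}: {exc}") from exc
        screen_df = pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "passed": r.passed,
                    "tm_count": r.tm_count,
                    "retinal_lysine_position": (
                        r.retinal_lysine_position + 1
                        if r.retinal_lysine_position is not None else ""
                    ),
                    "fail_reasons": ",".join(r.fail_reasons),
                }
                for r in results
            ],
            columns=SCHEMAS["screen_results"],
        )
        write_tsv(screen_df, outdir / "screen_results.tsv")
        passing_ids = {r.record_id for r in results if r.passed}
        passing = [r for r in records if r.id in passing_ids]
        logger.info("screen: %d of %d records pass", len(passing), len(records))

        # --- annotate ------------------------------------------------------
        stage = "annotate"
        call_rows = []
        calls = []
        for rec in passing:
            try:
                call = extract_motif(
                    rec, reference, config.align_params, config.min_identity
                )
                status = "ok"
            except UnalignableError:
                call = None
                status = "unalignable"
            except Exception as exc:
                raise PipelineError(stage, f"record {rec.id}: {exc}") from exc
            if call is not None:
                calls.append(call)
                call_rows.append(
                    {
                        "record_id": call.record_id,
                        "residue_97": call.residue_97 or MISSING_CHAR,
                        "residue_101": call.residue_101 or MISSING_CHAR,
                        "residue_105": call.residue_105 or MISSING_CHAR,
                        "residue_108": call.residue_108 or MISSING_CHAR,
                        "pump_motif": call.pump_motif,
                        "combined_label": call.combined_label,
                        "pump_class": call.pump_class,
                        "tuning_class": call.tuning_class,
                        "complete": call.complete,
                        "alignment_identity": call.alignment_identity,
                        "status": status,
                    }
                )
            else:
                call_rows.append(
                    {
                        "record_id": rec.id,
                        **{f"residue_{p}": MISSING_CHAR for p in (97, 101, 105, 108)},
                        "pump_motif": MISSING_CHAR * 3,
                        "combined_label": f"{MISSING_CHAR * 3}-{MISSING_CHAR}",
                        "pump_class": "unknown",
                        "tuning_class": "unknown",
                        "complete": False,
                        "alignment_identity": float("nan"),
                        "status": status,
                    }
                )
        motif_df = pd.DataFrame(call_rows, columns=SCHEMAS["motif_calls"])
        write_tsv(motif_df, outdir / "motif_calls.tsv")
        complete_calls = [c for c in calls if c.complete]
        logger.info(
            "annotate: %d calls, %d complete", len(call_rows), len(complete_calls)
        )

        # --- cluster -------------------------------------------------------
        stage = "cluster"
        cluster_rows = []
        if passing:
            try:
                clusters = greedy_cluster(
                    passing,
                    threshold=config.cluster_threshold,
                    level=config.cluster_level,
                    denominator=config.identity_denominator,
                )
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            for cl in clusters:
                for member, ident in zip(cl.member_ids, cl.identities):
                    cluster_rows.append(
                        {
                            "representative_id": cl.representative_id,
                            "member_id": member,
                            "identity": ident,
                        }
                    )
            logger.info(
                "cluster: %d representatives for %d sequences",
                len(clusters), len(passing),
            )
        cluster_df = pd.DataFrame(cluster_rows, columns=SCHEMAS["clusters"])
        write_tsv(cluster_df, outdir / "clusters.tsv")

        # --- abundance -----------------------------------------------------
        stage = "abundance"
        if config.coverage and config.metadata:
            try:
                coverage = read_tsv(config.coverage)
                metadata = read_tsv(config.metadata)
                table = CoverageTable(
                    coverage=coverage,
                    metadata=metadata[metadata["sample_id"].isin(coverage["sample_id"])],
                )
                gene_ids = [g for g in passing_ids if g in set(coverage["gene_id"])]
                profile = copy_number_profile(table, gene_ids, config.uscg_statistic)
                label_map = {
                    c.record_id: c.combined_label for c in complete_calls
                }
                by_label = relative_abundance(profile, label_map)
                depth_map = dict(
                    zip(table.metadata["sample_id"], table.metadata["depth_m"])
                )
                gene_rows = profile.assign(
                    depth_m=[depth_map[s] for s in profile["sample_id"]],
                    category_type="gene",
                    category=profile["gene_id"],
                    fraction=float("nan"),
                )[SCHEMAS["abundance"]]
                label_rows = by_label.assign(
                    depth_m=[depth_map[s] for s in by_label["sample_id"]],
                    category_type="motif",
                )[SCHEMAS["abundance"]]
                abundance_df = pd.concat([gene_rows, label_rows], ignore_index=True)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
        else:
            abundance_df = pd.DataFrame(columns=SCHEMAS["abundance"])
        write_tsv(abundance_df, outdir / "abundance.tsv")

        # --- expression ----------------------------------------------------
        stage = "expression"
        if config.transcripts and config.metadata:
            try:
                counts = read_tsv(config.transcripts)
                metadata = read_tsv(config.metadata)
                expr_df = transcript_summary(counts, metadata)[SCHEMAS["expression"]]
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
        else:
            expr_df = pd.DataFrame(columns=SCHEMAS["expression"])
        write_tsv(expr_df, outdir / "expression.tsv")

        # --- manifest and summary -----------------------------------------
        manifest = {
            "package": "rhodosurvey",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "config": asdict(config),
            "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
            "counts": {
                "records": len(records),
                "passed_screen": len(passing),
                "complete_motifs": len(complete_calls),
                "clusters": len({r["representative_id"] for r in cluster_rows}),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

        label_counts = pd.Series(
            [c.combined_label for c in complete_calls], dtype=str
        ).value_counts()
        with open(outdir / "summary.txt", "w") as fh:
            fh.write("rhodosurvey run summary\n")
            fh.write(f"records screened: {len(records)}\n")
            fh.write(f"passed 7-TM + retinal lysine screen: {len(passing)}\n")
            fh.write(f"complete four-site motifs: {len(complete_calls)}\n")
            fh.write(
                f"non-redundant representatives at "
                f"{config.cluster_threshold:.0%} identity: "
                f"{len({r['representative_id'] for r in cluster_rows})}\n"
            )
            fh.write("\nmotif frequency (complete sequences):\n")
            for label, count in label_counts.items():
                fh.write(f"  {label}\t{count}\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    marker.unlink()
    return outdir
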