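"""Synthetic opsins, decoys and community tables with planted truth.

Every downstream stage of the pipeline is testable offline against
sequences and tables whose true properties are planted by construction:

* :func:`make_opsin` mutates the bundled proteorhodopsin reference down
  to a requested identity while planting the four motif residues,
  keeping the retinal lysine and restricting substitutions so the
  seven-helix hydropathy topology survives (hydrophobic alphabet inside
  reference TM segments, hydrophilic outside). Each product is verified
  against the screen and the motif annotator before it is returned, so
  planted truth holds by construction; the verification re-draws from
  the same seeded stream, keeping outputs deterministic.
* :func:`make_decoy` builds the three control classes the screen must
  reject: a six-helix construct, a lysine-less opsin, and a soluble
  protein whose hydropathy never reaches the TM threshold.
* :func:`make_community_coverage` and :func:`make_transcript_counts`
  emit coverage/read-count tables in which copies-per-genome and
  transcript fractions are planted exactly (noise "none") or under
  Poisson / mean-one lognormal noise.

:func:`make_bundle` composes these into a depth-stratified survey whose
planted community structure echoes the study system: a SAR11-dominated
profile (60.9 % of rhodopsin copies), surface copy numbers near 0.7
falling to 0.15 per genome at depth, blue-absorbing DTE-Q motifs in
shallow samples and the uncharacterised DTT-T type at depth, and
transcript fractions from 0.02 % at the surface to 0.001 % below 500 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .abundance import USCG_IDS, CoverageTable
from .hydropathy import DEFAULT_TOPOLOGY, TopologyParams, call_topology
from .motifs import classify_pump, classify_tuning, extract_motif
from .records import AA20, ProteinRecord, write_fasta, write_tsv
from .reference import ReferenceFrame, load_reference
from .screen import screen_opsin

#: residues allowed as substitutions inside reference TM segments
HYDROPHOBIC = "AFILMVW"
#: residues allowed as substitutions in loops (all Kyte–Doolittle < 0)
LOOP_ALPHABET = "DEGHKNPQRSTY"
#: alphabet of the soluble decoy (max hydropathy G = -0.4 < threshold)
SOLUBLE_ALPHABET = "DEGHKNPQRSTY"

DECOY_KINDS = ("six_tm", "no_lysine", "soluble")
NOISE_MODELS = ("none", "poisson", "lognormal")

_REFERENCE_CACHE: dict[tuple, ReferenceFrame] = {}


def _default_reference(params: TopologyParams = DEFAULT_TOPOLOGY) -> ReferenceFrame:
    key = (params.window, params.threshold, params.min_tm_length, params.merge_gap)
    if key not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[key] = load_reference(topology_params=params)
    return _REFERENCE_CACHE[key]


@dataclass
class SyntheticTruth:
    """Planted parameters of one generated artefact (the test oracle)."""

    record_id: str
    is_opsin: bool
    rng_seed: int
    #: residues planted at PR positions (97, 101, 105, 108); None for decoys
    planted_motif: Optional[tuple[str, str, str, str]] = None
    tm_segment_count: Optional[int] = None
    retinal_lysine_present: Optional[bool] = None
    target_identity_to_reference: Optional[float] = None
    decoy_kind: Optional[str] = None
    #: (sample_id, gene_id) → copies per genome, for coverage truth entries
    planted_copies_per_genome: Optional[dict[tuple[str, str], float]] = None
    #: sample_id → percent of non-rRNA reads, for transcript truth entries
    planted_transcript_fraction: Optional[dict[str, float]] = None

    @property
    def combined_label(self) -> Optional[str]:
        if self.planted_motif is None:
            return None
        r97, r101, r105, r108 = self.planted_motif
        return f"{r97}{r101}{r108}-{r105}"


def _validate_motif(motif: Sequence[str]) -> tuple[str, str, str, str]:
    motif = tuple(str(m).upper() for m in motif)
    if len(motif) != 4:
        raise ValueError(f"motif must have 4 residues (97/101/105/108), got {len(motif)}")
    bad = [m for m in motif if m not in AA20]
    if bad:
        raise ValueError(f"non-standard motif residue(s): {', '.join(bad)}")
    return motif


def make_opsin(
    target_identity: float,
    motif: Sequence[str],
    seed: int,
    scaffold: Optional[ReferenceFrame] = None,
    record_id: Optional[str] = None,
    sample_id: str = "",
    depth_m: Optional[float] = None,
    taxon: Optional[str] = None,
    topology_params: TopologyParams = DEFAULT_TOPOLOGY,
    max_attempts: int = 50,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Plant a motif into a mutated copy of the reference scaffold.

    ``motif`` gives the residues at PR positions (97, 101, 105, 108).
    The realised identity to the scaffold is within ±0.03 of
    ``target_identity`` (exact up to rounding of the mutation count);
    the retinal lysine and a ±3 flank are never touched.
    """
    if not 0.3 <= target_identity <= 1.0:
        raise ValueError(f"target_identity {target_identity} outside [0.3, 1.0]")
    motif = _validate_motif(motif)
    if scaffold is None:
        scaffold = _default_reference(topology_params)
    ref_seq = scaffold.aa_sequence
    L = len(ref_seq)
    motif_idx = [p - 1 for p in scaffold.motif_positions_pr]
    lys_idx = scaffold.retinal_lysine_pr - 1
    protected = set(motif_idx) | set(range(lys_idx - 3, lys_idx + 4))
    in_tm = np.zeros(L, dtype=bool)
    for s, e in scaffold.tm_segments:
        in_tm[s:e] = True
    free = [i for i in range(L) if i not in protected]

    n_target = round((1.0 - target_identity) * L)
    rng = np.random.default_rng(seed)
    rec_id = record_id or f"syn_opsin_{seed}"

    for attempt in range(max_attempts):
        seq = list(ref_seq)
        for i, m in zip(motif_idx, motif):
            seq[i] = m
        mismatches = sum(1 for i in motif_idx if seq[i] != ref_seq[i])
        extra = max(0, n_target - mismatches)
        positions = rng.choice(len(free), size=min(extra, len(free)), replace=False)
        for k in positions:
            i = free[k]
            pool = HYDROPHOBIC if in_tm[i] else LOOP_ALPHABET
            choices = [c for c in pool if c != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
        candidate = "".join(seq)
        realized = sum(a == b for a, b in zip(candidate, ref_seq)) / L
        if abs(realized - target_identity) > 0.03:
            continue
        record = ProteinRecord(
            id=rec_id, aa_sequence=candidate, sample_id=sample_id,
            depth_m=depth_m, taxon=taxon,
        )
        # planted truth must hold by construction: verify, else re-draw
        result = screen_opsin(record, scaffold, topology_params)
        if not result.passed:
            continue
        call = extract_motif(record, scaffold)
        got = (call.residue_97, call.residue_101, call.residue_105, call.residue_108)
        if got != motif:
            continue
        truth = SyntheticTruth(
            record_id=rec_id,
            is_opsin=True,
            rng_seed=seed,
            planted_motif=motif,
            tm_segment_count=7,
            retinal_lysine_present=True,
            target_identity_to_reference=target_identity,
        )
        return record, truth
    raise RuntimeError(
        f"could not realise an opsin at identity {target_identity} in "
        f"{max_attempts} attempts (seed {seed})"
    )


def make_decoy(
    kind: str,
    seed: int,
    scaffold: Optional[ReferenceFrame] = None,
    record_id: Optional[str] = None,
    topology_params: TopologyParams = DEFAULT_TOPOLOGY,
    max_attempts: int = 50,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Build one non-opsin control of the named class.

    ``six_tm`` erases the seventh TM segment (hydrophilic residues,
    retinal lysine kept); ``no_lysine`` substitutes the retinal lysine
    to alanine; ``soluble`` is a random hydrophilic protein with no
    window above the TM threshold.
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}; expected one of {DECOY_KINDS}")
    if scaffold is None:
        scaffold = _default_reference(topology_params)
    ref_seq = scaffold.aa_sequence
    lys_idx = scaffold.retinal_lysine_pr - 1
    rng = np.random.default_rng(seed)
    rec_id = record_id or f"syn_decoy_{kind}_{seed}"

    for attempt in range(max_attempts):
        if kind == "six_tm":
            # wipe everything from the start of the last TM segment to the
            # C-terminus, keeping only the lysine itself
            start = scaffold.tm_segments[-1][0]
            seq = list(ref_seq)
            for i in range(start, len(seq)):
                if i != lys_idx:
                    seq[i] = SOLUBLE_ALPHABET[rng.integers(len(SOLUBLE_ALPHABET))]
            candidate = "".join(seq)
            expect_tm, lys_present = 6, True
        elif kind == "no_lysine":
            seq = list(ref_seq)
            seq[lys_idx] = "A"
            candidate = "".join(seq)
            expect_tm, lys_present = 7, False
        else:  # soluble
            n = len(ref_seq)
            idx = rng.integers(len(SOLUBLE_ALPHABET), size=n)
            candidate = "".join(SOLUBLE_ALPHABET[i] for i in idx)
            expect_tm, lys_present = 0, False

        record = ProteinRecord(id=rec_id, aa_sequence=candidate)
        topo = call_topology(candidate, topology_params)
        if kind == "six_tm" and topo.tm_count != 6:
            continue
        if kind == "soluble" and topo.tm_count != 0:
            continue
        result = screen_opsin(record, scaffold, topology_params)
        if result.passed:
            continue
        truth = SyntheticTruth(
            record_id=rec_id,
            is_opsin=False,
            rng_seed=seed,
            tm_segment_count=topo.tm_count,
            retinal_lysine_present=lys_present,
            decoy_kind=kind,
        )
        return record, truth
    raise RuntimeError(f"could not realise a {kind} decoy in {max_attempts} attempts")


def make_community_coverage(
    n_samples: int,
    depths: Sequence[float],
    planted: Mapping[str, Union[float, Sequence[float]]],
    uscg_mean_coverage: float = 500.0,
    noise: str = "none",
    seed: int = 0,
    lognormal_sigma: float = 0.2,
    date: str = "2020-01-01",
) -> tuple[CoverageTable, SyntheticTruth]:
    """Coverage table with planted copies-per-genome.

    ``planted`` maps gene_id to a scalar (same in every sample) or a
    per-sample sequence of copies per genome. Under ``noise='none'``
    every downstream estimate recovers the planted value exactly;
    ``'poisson'`` draws integer coverages, ``'lognormal'`` applies
    mean-one multiplicative noise with the given sigma.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(depths) != n_samples:
        raise ValueError(f"{len(depths)} depths for {n_samples} samples")
    if not planted:
        raise ValueError("planted gene map is empty")
    if uscg_mean_coverage <= 0:
        raise ValueError("uscg_mean_coverage must be positive")
    if noise not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise!r}; expected one of {NOISE_MODELS}")

    expanded: dict[str, list[float]] = {}
    for gene, value in planted.items():
        if np.isscalar(value):
            vals = [float(value)] * n_samples
        else:
            vals = [float(v) for v in value]
            if len(vals) != n_samples:
                raise ValueError(f"{gene}: {len(vals)} planted values for {n_samples} samples")
        if any(v < 0 for v in vals):
            raise ValueError(f"{gene}: negative copies_per_genome")
        expanded[gene] = vals

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{k + 1:02d}" for k in range(n_samples)]

    def _noised(base: float) -> float:
        if noise == "none":
            return base
        if noise == "poisson":
            return float(rng.poisson(base))
        factor = rng.lognormal(mean=-lognormal_sigma**2 / 2, sigma=lognormal_sigma)
        return base * factor

    rows = []
    truth_map: dict[tuple[str, str], float] = {}
    for k, sid in enumerate(sample_ids):
        for cog in USCG_IDS:
            cov = _noised(uscg_mean_coverage)
            # the normalisation contract requires positive marker coverage
            if cov <= 0:
                cov = 1.0
            rows.append((sid, cog, cov, True))
        for gene, vals in expanded.items():
            cpg = vals[k]
            rows.append((sid, gene, _noised(cpg * uscg_mean_coverage), False))
            truth_map[(sid, gene)] = cpg
    coverage = pd.DataFrame(rows, columns=["sample_id", "gene_id", "coverage", "is_uscg"])
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "depth_m": [float(d) for d in depths], "date": date}
    )
    table = CoverageTable(coverage=coverage, metadata=metadata)
    truth = SyntheticTruth(
        record_id=f"coverage_seed{seed}",
        is_opsin=False,
        rng_seed=seed,
        planted_copies_per_genome=truth_map,
    )
    return table, truth


def make_transcript_counts(
    planted_fraction_percent: Union[float, Sequence[float]],
    total_reads: int,
    seed: int = 0,
    noise: str = "binomial",
    sample_ids: Optional[Sequence[str]] = None,
    depths: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Read-count table with planted transcript fractions (percent).

    ``noise='binomial'`` draws the rhodopsin-mapped count from
    Binomial(total_reads, fraction/100); ``'none'`` rounds
    deterministically.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if noise not in ("binomial", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    fracs = (
        [float(planted_fraction_percent)]
        if np.isscalar(planted_fraction_percent)
        else [float(f) for f in planted_fraction_percent]
    )
    for f in fracs:
        if not 0 <= f <= 100:
            raise ValueError(f"transcript fraction {f} outside [0, 100]")
    if sample_ids is None:
        sample_ids = [f"T{k + 1:02d}" for k in range(len(fracs))]
    if len(sample_ids) != len(fracs):
        raise ValueError("sample_ids length does not match fractions")
    rng = np.random.default_rng(seed)
    counts = []
    for f in fracs:
        p = f / 100.0
        if noise == "binomial":
            counts.append(int(rng.binomial(total_reads, p)))
        else:
            counts.append(int(round(total_reads * p)))
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "rhodopsin_reads": counts,
            "total_nonrrna_reads": total_reads,
        }
    )
    if depths is not None:
        df["depth_m"] = [float(d) for d in depths]
    truth = SyntheticTruth(
        record_id=f"transcripts_seed{seed}",
        is_opsin=False,
        rng_seed=seed,
        planted_transcript_fraction=dict(zip(sample_ids, fracs)),
    )
    return df, truth


def make_banded_clusters(
    seed: int,
    group_sizes: Sequence[int] = (8, 6, 4, 2),
    length: int = 80,
    max_mutations: int = 1,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> tuple[list[tuple[str, str]], list[set[str]]]:
    """Sequences planted as identity-separated groups, for clustering tests.

    Each group is a random centroid plus members with at most
    ``max_mutations`` substitutions (within-group identity
    >= 1 - 2*max_mutations/length); distinct random centroids keep
    between-group identity far below any dereplication threshold.
    Returns ``(records, partition)`` where records are (id, sequence)
    pairs and partition is the list of planted member-id sets.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    partition: list[set[str]] = []
    for g, size in enumerate(group_sizes):
        centroid = "".join(
            alphabet[i] for i in rng.integers(len(alphabet), size=length)
        )
        group: set[str] = set()
        for m in range(size):
            seq = list(centroid)
            for pos in rng.choice(length, size=rng.integers(0, max_mutations + 1), replace=False):
                choices = [c for c in alphabet if c != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
            rec_id = f"g{g}m{m}"
            records.append((rec_id, "".join(seq)))
            group.add(rec_id)
        partition.append(group)
    return records, partition


# --- depth-stratified survey bundle -----------------------------------------

#: planted total proteorhodopsin copies per genome at each sampled depth
TOTAL_PR_CPG = {25.0: 0.70, 75.0: 0.65, 125.0: 0.55, 200.0: 0.35,
                500.0: 0.20, 770.0: 0.18, 1000.0: 0.15}

#: planted taxon shares of rhodopsin copies (SAR11-dominated community)
TAXON_WEIGHTS = {
    "SAR11": 0.609, "Bacteroidetes": 0.07, "unassigned": 0.07,
    "SAR324": 0.05, "SUP05": 0.04, "SAR116": 0.04, "SAR86": 0.04,
    "Actinobacteria": 0.03, "Euryarchaeota": 0.03, "other": 0.021,
}

#: motif palette (residues at 97/101/105/108) with sampling weights
MOTIF_PALETTE = [
    (("D", "T", "Q", "E"), 0.45),  # DTE-Q  blue proton pump
    (("D", "T", "T", "T"), 0.20),  # DTT-T  deep-water, unknown function
    (("D", "T", "L", "E"), 0.08),  # DTE-L  green proton pump
    (("D", "T", "M", "E"), 0.07),  # DTE-M  green proton pump
    (("D", "T", "Q", "Q"), 0.08),  # DTQ-Q  deep proton pump
    (("N", "D", "L", "Q"), 0.06),  # NDQ-L  sodium pump
    (("N", "T", "Q", "Q"), 0.06),  # NTQ-Q  chloride pump
]

#: planted retinal/carotenoid biosynthesis copy numbers per depth
RETINAL_GENE_CPG = {
    "blh":   {25.0: 0.50, 75.0: 0.45, 125.0: 0.40, 200.0: 0.25, 500.0: 0.10, 770.0: 0.08, 1000.0: 0.05},
    "crtB":  {25.0: 0.30, 75.0: 0.28, 125.0: 0.26, 200.0: 0.20, 500.0: 0.12, 770.0: 0.10, 1000.0: 0.08},
    "crtI":  {d: 0.30 for d in TOTAL_PR_CPG},
    "crtY":  {25.0: 0.22, 75.0: 0.20, 125.0: 0.18, 200.0: 0.14, 500.0: 0.10, 770.0: 0.08, 1000.0: 0.06},
    "diox1": {d: 0.10 for d in TOTAL_PR_CPG},
}

#: planted transcript fractions (percent of non-rRNA reads) by depth
TRANSCRIPT_FRACTION_PCT = {15.0: 0.02, 200.0: 0.004, 500.0: 0.001, 770.0: 0.001, 1000.0: 0.001}


@dataclass
class SyntheticBundle:
    """A complete seeded survey: sequences, tables, and all planted truth."""

    records: list[ProteinRecord]
    truths: dict[str, SyntheticTruth]
    coverage_table: CoverageTable
    coverage_truth: SyntheticTruth
    transcripts: pd.DataFrame
    transcript_truth: SyntheticTruth
    taxon_map: dict[str, str]
    motif_map: dict[str, str]
    gene_sets: dict[str, list[str]]
    seed: int

    @property
    def opsin_ids(self) -> list[str]:
        return [r.id for r in self.records if self.truths[r.id].is_opsin]

    @property
    def decoy_ids(self) -> list[str]:
        return [r.id for r in self.records if not self.truths[r.id].is_opsin]


def _quota_counts(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over weighted bins."""
    raw = {k: w * n for k, w in weights.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    leftovers = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in leftovers[:short]:
        counts[k] += 1
    return counts


def make_bundle(
    n_opsins: int = 40,
    n_decoys: int = 12,
    seed: int = 0,
    identity_range: tuple[float, float] = (0.70, 0.95),
    uscg_mean_coverage: float = 500.0,
    noise: str = "none",
    total_transcript_reads: int = 10_000_000,
    transcript_noise: str = "none",
) -> SyntheticBundle:
    """Generate a full depth-stratified synthetic survey."""
    if n_opsins < 1:
        raise ValueError("need at least one opsin")
    rng = np.random.default_rng(seed)
    scaffold = _default_reference()

    taxon_counts = _quota_counts(TAXON_WEIGHTS, n_opsins)
    taxa = [t for t, c in taxon_counts.items() for _ in range(c)]
    motif_weights = np.array([w for _, w in MOTIF_PALETTE])
    motif_weights = motif_weights / motif_weights.sum()

    records: list[ProteinRecord] = []
    truths: dict[str, SyntheticTruth] = {}
    taxon_map: dict[str, str] = {}
    motif_map: dict[str, str] = {}
    for k in range(n_opsins):
        motif = MOTIF_PALETTE[rng.choice(len(MOTIF_PALETTE), p=motif_weights)][0]
        ident = float(rng.uniform(*identity_range))
        sub_seed = int(rng.integers(2**31 - 1))
        rec, truth = make_opsin(
            target_identity=ident, motif=motif, seed=sub_seed,
            scaffold=scaffold, record_id=f"PR{k + 1:04d}", taxon=taxa[k],
        )
        records.append(rec)
        truths[rec.id] = truth
        taxon_map[rec.id] = taxa[k]
        motif_map[rec.id] = truth.combined_label
    for k in range(n_decoys):
        kind = DECOY_KINDS[k % len(DECOY_KINDS)]
        sub_seed = int(rng.integers(2**31 - 1))
        rec, truth = make_decoy(
            kind=kind, seed=sub_seed, scaffold=scaffold,
            record_id=f"DECOY{k + 1:03d}",
        )
        records.append(rec)
        truths[rec.id] = truth

    # per-gene copies per genome: depth total × taxon share / genes in taxon
    depths = sorted(TOTAL_PR_CPG)
    taxon_sizes = {t: taxa.count(t) for t in taxon_counts}
    planted: dict[str, list[float]] = {}
    for rec_id, taxon in taxon_map.items():
        planted[rec_id] = [
            TOTAL_PR_CPG[d] * TAXON_WEIGHTS[taxon] / taxon_sizes[taxon] for d in depths
        ]
    for gene, by_depth in RETINAL_GENE_CPG.items():
        planted[gene] = [by_depth[d] for d in depths]
    cov_seed = int(rng.integers(2**31 - 1))
    coverage_table, coverage_truth = make_community_coverage(
        n_samples=len(depths), depths=depths, planted=planted,
        uscg_mean_coverage=uscg_mean_coverage, noise=noise, seed=cov_seed,
    )

    tx_depths = sorted(TRANSCRIPT_FRACTION_PCT)
    tx_seed = int(rng.integers(2**31 - 1))
    transcripts, transcript_truth = make_transcript_counts(
        planted_fraction_percent=[TRANSCRIPT_FRACTION_PCT[d] for d in tx_depths],
        total_reads=total_transcript_reads, seed=tx_seed, noise=transcript_noise,
        sample_ids=[f"TX{int(d)}m" for d in tx_depths], depths=tx_depths,
    )

    gene_sets = {name: [name] for name in RETINAL_GENE_CPG}
    gene_sets["PR"] = [r for r in taxon_map]
    return SyntheticBundle(
        records=records,
        truths=truths,
        coverage_table=coverage_table,
        coverage_truth=coverage_truth,
        transcripts=transcripts,
        transcript_truth=transcript_truth,
        taxon_map=taxon_map,
        motif_map=motif_map,
        gene_sets=gene_sets,
        seed=seed,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle as FASTA + TSV files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "coverage": outdir / "coverage.tsv",
        "metadata": outdir / "metadata.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "truth": outdir / "truth_records.tsv",
        "truth_coverage": outdir / "truth_coverage.tsv",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
    }
    write_fasta(bundle.records, paths["fasta"])
    write_tsv(bundle.coverage_table.coverage, paths["coverage"])
    tx_meta = bundle.transcripts[["sample_id", "depth_m"]].assign(date="")
    metadata = pd.concat(
        [bundle.coverage_table.metadata, tx_meta], ignore_index=True
    )
    write_tsv(metadata, paths["metadata"])
    write_tsv(
        bundle.transcripts[["sample_id", "rhodopsin_reads", "total_nonrrna_reads"]],
        paths["transcripts"],
    )
    truth_rows = []
    for rec in bundle.records:
        t = bundle.truths[rec.id]
        truth_rows.append(
            {
                "record_id": t.record_id,
                "is_opsin": t.is_opsin,
                "decoy_kind": t.decoy_kind or "",
                "planted_motif": "".join(t.planted_motif) if t.planted_motif else "",
                "combined_label": t.combined_label or "",
                "tm_segment_count": t.tm_segment_count,
                "retinal_lysine_present": t.retinal_lysine_present,
                "target_identity": t.target_identity_to_reference,
                "taxon": bundle.taxon_map.get(rec.id, ""),
                "rng_seed": t.rng_seed,
            }
        )
    write_tsv(pd.DataFrame(truth_rows), paths["truth"])
    cov_rows = [
        {"sample_id": s, "gene_id": g, "copies_per_genome": v}
        for (s, g), v in sorted(bundle.coverage_truth.planted_copies_per_genome.items())
    ]
    write_tsv(pd.DataFrame(cov_rows), paths["truth_coverage"])
    tx_rows = [
        {"sample_id": s, "fraction_percent": f}
        for s, f in bundle.transcript_truth.planted_transcript_fraction.items()
    ]
    write_tsv(pd.DataFrame(tx_rows), paths["truth_transcripts"])
    return paths
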