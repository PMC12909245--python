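"""End-to-end pipeline: build profiles, scan, classify, count, map, tree.

Each stage reads and writes plain files in the output directory, so any
stage can be rerun standalone; a provenance manifest stamps every run
with the configuration values and seed actually used.  Reruns with the
same config and seed are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import architecture, genome_map, io_formats, phylogeny, profile_hmm, repertoire

log = logging.getLogger("nlrkit")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the documented defaults."""

    # paths
    seed_alignment_dir: str = ""  # aligned FASTA per domain: <DOMAIN>.afa
    proteome: str = ""  # protein FASTA
    gff: str = ""  # optional gene coordinates
    output_dir: str = "nlrkit_out"
    species: str = ""

    # profile construction / scanning
    gap_fraction_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    alpha: float = 1e-3
    calibration_shuffles: int = 500
    calibration_length: tuple[int, int] = (100, 600)
    select_block: bool = False
    block_min_occupancy: float = 0.5
    block_min_run: int = 10

    # architecture
    max_overlap_frac: float = 0.5
    domain_roles: dict[str, str] = field(
        default_factory=lambda: {f"LRR_{i}": "LRR" for i in (1, 2, 3, 4, 6)}
    )

    # genome map
    max_gap_bp: int = 100_000
    min_cluster_size: int = 2
    min_identity: float = 90.0
    gff_feature_type: str = "gene"
    gff_id_attribute: str = "ID"
    id_suffix_strip: str = ""

    # phylogeny
    bootstrap_replicates: int = 100
    distance_model: str = "poisson"
    nacht_flank: int = 0
    outgroup: tuple[str, ...] = ()

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "calibration_length" in data:
            data["calibration_length"] = tuple(data["calibration_length"])
        if "outgroup" in data:
            data["outgroup"] = tuple(data["outgroup"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


STAGES = ("build-profile", "scan", "classify", "repertoire", "map", "phylo")


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] = STAGES,
    dry_run: bool = False,
) -> Path:
    """Run the requested stages in canonical order; returns the output dir.

    Any stage failure raises with the stage name and offending input
    path.  ``dry_run`` logs the stage plan without writing anything.
    """
    order = [s for s in STAGES if s in stages]
    out = Path(config.output_dir)
    if "map" in order and not config.gff:
        raise ValueError("stage 'map' requested but config.gff is not set")
    if dry_run:
        for s in order:
            log.info("DRY RUN stage: %s", s)
        return out
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": order,
    }
    (out / "provenance.json").write_text(json.dumps(manifest, indent=1, default=str))

    state: dict = {}
    for stage in order:
        log.info("stage %s starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done", stage)
    return out


def _load_profiles(config: PipelineConfig, out: Path) -> list[profile_hmm.ProfileHMM]:
    prof_dir = out / "profiles"
    profiles = []
    for path in sorted(prof_dir.glob("*.json")):
        profiles.append(profile_hmm.ProfileHMM.from_json(path))
    if not profiles:
        raise FileNotFoundError(f"no profiles in {prof_dir}; run build-profile first")
    return profiles


def _stage_build_profile(config: PipelineConfig, out: Path, state: dict) -> None:
    seed_dir = Path(config.seed_alignment_dir)
    files = sorted(
        list(seed_dir.glob("*.afa")) + list(seed_dir.glob("*.fasta")) + list(seed_dir.glob("*.fa"))
    )
    if not files:
        raise FileNotFoundError(f"no seed alignments (*.afa/*.fasta/*.fa) in {seed_dir}")
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    profiles = []
    for f in files:
        msa = profile_hmm.read_alignment_fasta(f)
        if config.select_block:
            msa = profile_hmm.select_conserved_block(
                msa, config.block_min_occupancy, config.block_min_run
            )
        prof = profile_hmm.build_profile(
            msa,
            name=f.stem,
            gap_fraction_threshold=config.gap_fraction_threshold,
            pseudocount_weight=config.pseudocount_weight,
        )
        log.info(
            "profile %s: L=%d (gap threshold %.2f, pseudocount %.2f)",
            prof.name, prof.L, config.gap_fraction_threshold, config.pseudocount_weight,
        )
        profile_hmm.calibrate_null(
            prof,
            config.calibration_length,
            n_shuffles=config.calibration_shuffles,
            seed=config.seed,
            alpha=config.alpha,
        )
        log.info(
            "profile %s calibrated: threshold %.2f bits at alpha %g (%d shuffles)",
            prof.name, prof.null.threshold_bits, config.alpha, config.calibration_shuffles,
        )
        prof.to_json(prof_dir / f"{prof.name}.json")
        profiles.append(prof)
    state["profiles"] = profiles


def _stage_scan(config: PipelineConfig, out: Path, state: dict) -> None:
    profiles = state.get("profiles") or _load_profiles(config, out)
    proteome = io_formats.read_fasta(config.proteome, species=config.species)
    log.info("scanning %d proteins with %d profiles at alpha %g",
             len(proteome), len(profiles), config.alpha)
    hits = profile_hmm.scan_proteome(profiles, proteome, alpha=config.alpha)
    io_formats.write_hit_table(hits, out / "hits.tsv")
    state["hits"] = hits
    state["proteome"] = proteome


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> None:
    hits = state.get("hits")
    if hits is None:
        hits = io_formats.read_hit_table(out / "hits.tsv")
    token_map = architecture.TokenMap(config.domain_roles)
    records = architecture.classify_hit_table(
        hits,
        max_overlap_frac=config.max_overlap_frac,
        token_map=token_map,
        species=config.species,
    )
    architecture.records_to_frame(records).to_csv(
        out / "classified.tsv", sep="\t", index=False
    )
    log.info(
        "classified %d proteins (max_overlap_frac %.2f)", len(records), config.max_overlap_frac
    )
    state["records"] = records


def _stage_repertoire(config: PipelineConfig, out: Path, state: dict) -> None:
    hits = state.get("hits")
    if hits is None:
        hits = io_formats.read_hit_table(out / "hits.tsv")
    table = repertoire.count_domain_genes(hits, species=config.species or "sample")
    table.to_tsv(out / "repertoire.tsv")


def _stage_map(config: PipelineConfig, out: Path, state: dict) -> None:
    records = state.get("records")
    if records is None:
        raise FileNotFoundError("classify stage output missing (run classify first)")
    loci = io_formats.read_gff3(
        config.gff, feature_type=config.gff_feature_type, id_attribute=config.gff_id_attribute
    )
    located, unplaced = genome_map.assign_loci(records, loci)
    log.info(
        "located %d / %d genes; max_gap_bp %d, min_identity %.1f",
        len(located), len(records), config.max_gap_bp, config.min_identity,
    )
    clusters = genome_map.detect_clusters(
        located, max_gap_bp=config.max_gap_bp, min_size=config.min_cluster_size
    )
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("chromosome\tcategory\tn_genes\tstart\tend\tgenes\n")
        for c in clusters:
            fh.write(
                f"{c.chromosome}\t{c.category.value}\t{len(c.genes)}\t"
                f"{c.start}\t{c.end}\t{','.join(c.genes)}\n"
            )
    proteome = state.get("proteome")
    if proteome is None:
        proteome = io_formats.read_fasta(config.proteome, species=config.species)
    seqs = {p.id: p.sequence for p in proteome}
    bona_located = [l for l in located if l.category in architecture.BONA_FIDE]
    pairs = genome_map.find_near_duplicates(
        bona_located, seqs, identity_threshold=config.min_identity
    )
    with open(out / "duplicates.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tidentity\tsame_chromosome\tgenomic_gap\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.identity}\t{p.same_chromosome}\t"
                f"{'' if p.genomic_gap is None else p.genomic_gap}\n"
            )
    chrom_lengths: dict[str, int] = {}
    for loc in loci:
        chrom_lengths[loc.chromosome] = max(
            chrom_lengths.get(loc.chromosome, 0), loc.end
        )
    genome_map.export_ideogram(
        located, chrom_lengths, out / "karyotype.tsv", out / "ideogram_marks.tsv"
    )
    state["located"] = located


def _stage_phylo(config: PipelineConfig, out: Path, state: dict) -> None:
    records = state.get("records")
    hits = state.get("hits")
    proteome = state.get("proteome")
    if records is None or hits is None or proteome is None:
        raise FileNotFoundError("phylo stage needs scan + classify outputs in this run")
    token_map = architecture.TokenMap(config.domain_roles)
    by_protein: dict[str, list[io_formats.DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    seqs = {p.id: p for p in proteome}
    nacht_regions: dict[str, str] = {}
    meta: dict[str, architecture.NLRRecord] = {}
    for rec in records:
        if rec.category not in architecture.BONA_FIDE:
            continue
        nacht_hits = [
            h for h in by_protein.get(rec.gene_id, [])
            if token_map.token(h.model) == "NACHT"
        ]
        if not nacht_hits:
            continue
        best = max(nacht_hits, key=lambda h: h.bitscore)
        nacht_regions[rec.gene_id] = profile_hmm.extract_domain_region(
            seqs[rec.gene_id], best, flank=config.nacht_flank
        )
        meta[rec.gene_id] = rec
    if len(nacht_regions) < 3:
        log.warning("phylo: only %d bona fide NACHT regions; skipping tree", len(nacht_regions))
        return
    msa = phylogeny.align_domains(nacht_regions)
    phylogeny.write_phylip(msa, out / "nacht_alignment.phy")
    log.info(
        "phylo: %d sequences, %d replicates, %s distances",
        len(nacht_regions), config.bootstrap_replicates, config.distance_model,
    )
    tree = phylogeny.bootstrap_support(
        msa,
        n_replicates=config.bootstrap_replicates,
        seed=config.seed,
        model=config.distance_model,
    )
    (out / "nacht_tree.nwk").write_text(phylogeny.tree_to_newick(tree) + "\n")
    with open(out / "leaf_annotation.tsv", "w") as fh:
        fh.write("gene_id\tspecies\tcategory\tlrr_count\n")
        for gid, rec in sorted(meta.items()):
            fh.write(f"{gid}\t{rec.species}\t{rec.category.value}\t{rec.lrr_count}\n")
    state["tree"] = tree


_STAGE_FUNCS = {
    "build-profile": _stage_build_profile,
    "scan": _stage_scan,
    "classify": _stage_classify,
    "repertoire": _stage_repertoire,
    "map": _stage_map,
    "phylo": _stage_phylo,
}
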