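"""End-to-end pipeline orchestration from a single structured config.

Stages run in dependency order: identification -> physicochemical
profiling / phylogeny -> Ka/Ks / collinearity / gene structure ->
expression / qPCR statistics.  Every stage writes a TSV (header comment
with parameters and version) into the output directory; the run returns a
manifest of artifact paths and SHA-256 hashes, so identical config + seed
gives identical hashes.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import center_star_msa, pairwise_align
from .duplication_synteny import classify_pairs, default_homeolog_map, find_blocks
from .expression_stats import (
    anova_duncan, cluster_genes, correlate, ddct, ddct_summary,
    normalize_expression,
)
from .family_identification import (
    IdentificationConfig, run_funnel, scan_motifs,
)
from .gene_structure import compare_structures
from .io_formats import (
    ValidationError, read_blast_tabular, read_domain_table, read_fasta,
    read_gff3,
)
from .molecular_evolution import codon_align, kaks
from .phylogeny import (
    MsaView, assign_groups, bootstrap_support, nj_tree,
    pairwise_poisson_distance,
)

logger = logging.getLogger("genefamkit")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    proteins: Path
    cds: Path
    gff: Path
    hits: Path
    domains: Path
    refs: Path
    ref_groups: Path
    homologs: Path
    tpm: Path | None = None
    qpcr: Path | None = None
    metals: Path | None = None
    outdir: Path = Path("genefamkit_out")
    seed: int = 0
    e_value_threshold: float = 1e-10
    required_domains: tuple[str, ...] = ("PF00122", "PF00702")
    bootstrap_replicates: int = 100
    min_anchors: int = 5
    max_gap: int = 25
    tandem_max_rank_gap: int = 2
    lambda_rate: float = 8.12e-9
    n_expression_clusters: int = 2
    alpha: float = 0.05

    _KNOWN = None  # filled after class creation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("proteins", "cds", "gff", "hits", "domains", "refs",
                    "ref_groups", "homologs", "tpm", "qpcr", "metals", "outdir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        if "required_domains" in raw:
            raw["required_domains"] = tuple(raw["required_domains"])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> tuple[list[str], list[str]]:
    """Return (errors, warnings); an empty error list means runnable."""
    errors: list[str] = []
    warnings: list[str] = []
    for key in ("proteins", "cds", "gff", "hits", "domains", "refs",
                "ref_groups", "homologs"):
        p = getattr(config, key)
        if p is None:
            errors.append(f"missing required input path: {key}")
        elif not Path(p).exists():
            errors.append(f"{key} path does not exist: {p}")
    for key in ("tpm", "qpcr", "metals"):
        p = getattr(config, key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} path does not exist: {p}")
    if config.e_value_threshold <= 0:
        errors.append("e_value_threshold must be > 0")
    if config.bootstrap_replicates < 1:
        errors.append("bootstrap_replicates must be >= 1")
    if config.lambda_rate <= 0:
        errors.append("lambda_rate must be > 0")
    if not (0 < config.alpha < 1):
        errors.append("alpha must be in (0, 1)")
    if config.min_anchors < 2:
        warnings.append("min_anchors < 2 admits degenerate collinear blocks")
    if config.tandem_max_rank_gap < 1:
        warnings.append("tandem_max_rank_gap < 1 disables tandem calls")
    return errors, warnings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _header(stage: str, params: dict) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# genefamkit {__version__} stage={stage} {kv}\n"


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: dict,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns {artifact name: sha256}. Partial outputs of a
    failing stage keep a ``.partial`` suffix."""
    errors, warnings = validate_config(config)
    for w in warnings:
        logger.warning(w)
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    stage = "load"
    try:
        proteins = read_fasta(config.proteins, "protein")
        cds = {r.id: r for r in read_fasta(config.cds, "cds")}
        genes = read_gff3(config.gff)
        hits = read_blast_tabular(config.hits)
        domains = read_domain_table(config.domains, "simple_tsv")
        refs = read_fasta(config.refs, "protein")
        ref_groups_df = pd.read_csv(config.ref_groups, sep="\t")
        reference_groups = {
            g: sub["reference_id"].tolist()
            for g, sub in ref_groups_df.groupby("group")}
        homologs = pd.read_csv(config.homologs, sep="\t")
        by_id = {p.id: p for p in proteins}

        # ---- identification ------------------------------------------------
        stage = "identify"
        ref_ids = tuple(r.id for r in refs)
        ident_cfg = IdentificationConfig(
            e_value_threshold=config.e_value_threshold,
            required_domains=frozenset(config.required_domains),
            reference_ids=ref_ids)
        pre = run_funnel(hits, domains, proteins, None, ident_cfg)
        cand_records = [by_id[c] for c in sorted(pre.domain_filtered)] + refs
        cand_tree = nj_tree(pairwise_poisson_distance(cand_records))
        funnel = run_funnel(hits, domains, proteins, cand_tree, ident_cfg)
        fam_rows = []
        for pid in sorted(funnel.collected):
            stage_reached = ("confirmed" if pid in funnel.confirmed else
                             "domain_filtered" if pid in funnel.domain_filtered
                             else "collected")
            motifs = (scan_motifs(by_id[pid]) if pid in by_id else None)
            fam_rows.append(dict(
                protein_id=pid, stage_reached=stage_reached,
                core_motifs=(motifs.core_motifs_present if motifs else None)))
        family = sorted(funnel.confirmed)
        manifest["family"] = out / "family.tsv"
        _write_tsv(pd.DataFrame(fam_rows), manifest["family"], "identify",
                   dict(evalue=config.e_value_threshold,
                        domains=",".join(sorted(config.required_domains))))

        # ---- physicochemical profiling -------------------------------------
        stage = "physchem"
        from .physchem import profile_table
        manifest["physchem"] = out / "physchem.tsv"
        _write_tsv(profile_table([by_id[f] for f in family]),
                   manifest["physchem"], stage, {})

        # ---- phylogeny ------------------------------------------------------
        stage = "phylogeny"
        fam_records = [by_id[f] for f in family] + refs
        ids_msa, rows_msa = center_star_msa(fam_records)
        msa = MsaView(tuple(ids_msa), tuple(rows_msa))
        tree, supports = bootstrap_support(
            msa, replicates=config.bootstrap_replicates, seed=config.seed)
        manifest["tree"] = out / "tree.nwk"
        manifest["tree"].write_text(tree.newick() + "\n")
        groups = assign_groups(tree, reference_groups)
        manifest["groups"] = out / "groups.tsv"
        _write_tsv(pd.DataFrame(sorted(groups.items()),
                                columns=["gene", "group"]),
                   manifest["groups"], stage,
                   dict(bootstrap=config.bootstrap_replicates, seed=config.seed))

        # ---- collinearity and duplication classification -------------------
        stage = "synteny"
        pair_list = [(a, b) for a, b in homologs.itertuples(index=False)
                     if a in family and b in family]
        all_pairs = [tuple(r) for r in homologs.itertuples(index=False)]
        blocks = find_blocks(genes, all_pairs, config.min_anchors, config.max_gap)
        homeo = default_homeolog_map(len({g.chromosome for g in genes}) // 2)
        calls = classify_pairs(genes, pair_list, blocks, homeolog_map=homeo,
                               tandem_max_rank_gap=config.tandem_max_rank_gap)
        manifest["blocks"] = out / "blocks.tsv"
        _write_tsv(pd.DataFrame([
            dict(chrom_a=b.chrom_a, chrom_b=b.chrom_b, n_anchors=b.score,
                 orientation=b.orientation) for b in blocks]),
            manifest["blocks"], stage,
            dict(min_anchors=config.min_anchors, max_gap=config.max_gap))
        label_of = {frozenset((c.gene_a, c.gene_b)): c.label for c in calls}

        # ---- Ka/Ks and dating ----------------------------------------------
        stage = "kaks"
        kaks_rows = []
        alignments: dict[frozenset, tuple[str, str]] = {}
        for a, b in pair_list:
            ra, rb = pairwise_align(by_id[a].sequence, by_id[b].sequence)[:2]
            alignments[frozenset((a, b))] = (ra, rb)
            aln = codon_align(cds[a], cds[b], ra, rb)
            res = kaks(aln, config.lambda_rate)
            kaks_rows.append(dict(
                gene_a=a, gene_b=b,
                duplicate_type=label_of.get(frozenset((a, b)), "dispersed"),
                ka=round(res.ka, 3), ks=round(res.ks, 3),
                ka_ks=(round(res.omega, 3) if res.omega is not None else None),
                positive_selection=res.positive_selection,
                divergence_time_mya=round(res.divergence_time_mya, 2)))
        manifest["kaks"] = out / "kaks.tsv"
        _write_tsv(pd.DataFrame(kaks_rows), manifest["kaks"], stage,
                   dict(lambda_rate=config.lambda_rate))

        # ---- gene structure -------------------------------------------------
        stage = "genestruct"
        gene_by_id = {g.gene_id: g for g in genes}
        struct_rows = []
        for a, b in pair_list:
            ra, rb = alignments[frozenset((a, b))]
            cmp_ = compare_structures(gene_by_id[a], gene_by_id[b], ra, rb)
            struct_rows.append(dict(
                gene_a=a, gene_b=b, n_exons_a=cmp_.n_exons_a,
                n_exons_b=cmp_.n_exons_b,
                shared_boundaries=cmp_.shared_boundaries,
                mechanisms=",".join(sorted(cmp_.mechanisms))))
        manifest["structures"] = out / "structures.tsv"
        _write_tsv(pd.DataFrame(struct_rows), manifest["structures"], stage, {})

        # ---- expression ------------------------------------------------------
        if config.tpm is not None:
            stage = "expression"
            tpm = pd.read_csv(config.tpm, sep="\t", index_col=0)
            em = normalize_expression(tpm)
            clusters = cluster_genes(em, k=config.n_expression_clusters)
            manifest["expression_clusters"] = out / "expression_clusters.tsv"
            _write_tsv(pd.DataFrame(sorted(clusters.items()),
                                    columns=["gene", "cluster"]),
                       manifest["expression_clusters"], stage,
                       dict(k=config.n_expression_clusters))

        # ---- qPCR statistics -------------------------------------------------
        if config.qpcr is not None:
            stage = "qpcr"
            qpcr = pd.read_csv(config.qpcr, sep="\t")
            folds = ddct(qpcr)
            summary = ddct_summary(folds)
            letter_rows = []
            for (gene, cultivar), sub in folds.groupby(["gene", "cultivar"]):
                groups_ = {t: s["fold"].tolist()
                           for t, s in sub.groupby("treatment")}
                res = anova_duncan(groups_, alpha=config.alpha)
                for t in sorted(groups_):
                    letter_rows.append(dict(
                        gene=gene, cultivar=cultivar, treatment=t,
                        mean_fold=round(res.means[t], 3),
                        letters=res.letters[t],
                        f=None if res.f_statistic is None else round(res.f_statistic, 3),
                        p=None if res.p_value is None else res.p_value))
            manifest["qpcr_rq"] = out / "qpcr_rq.tsv"
            _write_tsv(summary, manifest["qpcr_rq"], stage, dict(alpha=config.alpha))
            manifest["qpcr_letters"] = out / "qpcr_letters.tsv"
            _write_tsv(pd.DataFrame(letter_rows), manifest["qpcr_letters"],
                       stage, dict(alpha=config.alpha))

            if config.metals is not None:
                stage = "correlation"
                metals = pd.read_csv(config.metals, sep="\t")
                key = ["cultivar", "treatment", "replicate"]
                expr_wide = folds.pivot_table(index=key, columns="gene",
                                              values="fold")
                trait_cols = [c for c in metals.columns if c not in key]
                traits = metals.set_index(key)[trait_cols]
                traits = traits.loc[expr_wide.index]
                corr = correlate(expr_wide, traits)
                manifest["correlations"] = out / "correlations.tsv"
                _write_tsv(corr, manifest["correlations"], stage, {})
    except Exception:
        for name, path in manifest.items():
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        logger.error("pipeline failed in stage %r", stage)
        raise

    hashes = {name: _sha256(path) for name, path in sorted(manifest.items())}
    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("artifact\tpath\tsha256\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name].name}\t{hashes[name]}\n")
    return hashes
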