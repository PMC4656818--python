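"""End-to-end orchestration: DE -> Venn -> enrichment -> iTRAQ -> cross-omics -> semantics.

A flat YAML config names the inputs and thresholds; :func:`run_full_analysis`
executes the stages in the order of the underlying study design and writes
one results bundle plus a manifest (file checksums, thresholds, seed,
package version).  Any stage failure aborts with the stage name; partial
outputs are kept alongside a ``.partial`` marker file.

:func:`demo` generates a fully synthetic study (two tissues, an iTRAQ run
whose planted proteins coincide with planted up-regulated transcripts, a
pathway collection and a literature corpus) and runs the whole analysis on
it, so the complete flow is reproducible from nothing but a seed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import PathwayCollection, bimodal_classification, hypergeometric_enrichment, polarity_score
from .itraq import ReporterQuant, read_peptide_table
from .microarray_de import IntensityMatrix, ZRatioModel
from .semantics import Corpus, LsiModel
from .set_algebra import cross_omics_overlap, venn_partition
from .simulate import (
    simulate_expression_study,
    simulate_itraq_experiment,
    simulate_literature_corpus,
    simulate_pathway_annotation,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "demo"]


@dataclass
class AnalysisConfig:
    """Flat configuration of the full analysis; every threshold defaults to
    the study's published gate."""

    output_dir: str
    tissues: list[str]
    expression: dict[str, dict[str, str]]  # tissue -> {"control": path, "case": path}
    peptides: str | None = None
    pathways: str | None = None
    corpus: str | None = None
    queries: list[str] = field(default_factory=list)
    seed: int = 0
    zr_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    itraq_lo: float = 0.8
    itraq_hi: float = 1.2
    min_peptides: int = 1
    channel_mode: str = "any"
    enrichment_min_members: int = 2
    enrichment_p: float = 0.05
    lsi_k: int | None = None
    intensity_floor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("zr_threshold", "p_threshold", "fdr_threshold", "itraq_lo", "itraq_hi", "enrichment_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for tissue in self.tissues:
            if tissue not in self.expression:
                raise ValueError(f"no expression paths for tissue {tissue!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tissues = raw.pop("tissues")
        expression = {
            t: {"control": raw.pop(f"expression_{t}_control"), "case": raw.pop(f"expression_{t}_case")}
            for t in tissues
        }
        return cls(tissues=tissues, expression=expression, **raw)

    def to_yaml(self, path) -> None:
        flat = asdict(self)
        expr = flat.pop("expression")
        for t, paths in expr.items():
            flat[f"expression_{t}_control"] = paths["control"]
            flat[f"expression_{t}_case"] = paths["case"]
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")


def _load_tissue_matrix(cfg: AnalysisConfig, tissue: str) -> IntensityMatrix:
    parts = []
    for genotype in ("control", "case"):
        values = pd.read_csv(cfg.expression[tissue][genotype], sep="\t", index_col=0)
        meta = pd.DataFrame(
            {"genotype": genotype, "tissue": tissue, "replicate": range(1, len(values.columns) + 1)},
            index=values.columns,
        )
        parts.append(IntensityMatrix(values=values, sample_meta=meta))
    return IntensityMatrix.concat(parts)


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every configured stage and return the manifest dict."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = outdir / ".partial"
    partial_marker.touch()
    outputs: list[Path] = []
    stage = "setup"
    try:
        # --- differential expression per tissue ------------------------------
        stage = "microarray_de"
        signed_sets = {}
        de_results = {}
        for tissue in cfg.tissues:
            matrix = _load_tissue_matrix(cfg, tissue)
            res = ZRatioModel(matrix, floor=cfg.intensity_floor).fit(
                zr_threshold=cfg.zr_threshold,
                p_threshold=cfg.p_threshold,
                fdr_threshold=cfg.fdr_threshold,
            )
            de_results[tissue] = res
            path = outdir / f"de_{_slug(tissue)}.tsv"
            res.to_tsv(path)
            outputs.append(path)
            signed_sets[tissue] = res.signed_set(tissue)

        # --- signed Venn partition across tissues ----------------------------
        stage = "set_algebra"
        if len(cfg.tissues) >= 2:
            part = venn_partition([signed_sets[t] for t in cfg.tissues])
            path = outdir / "venn_regions.tsv"
            part.to_frame().to_csv(path, sep="\t", index=False)
            outputs.append(path)
            path = outdir / "venn_counts.json"
            path.write_text(part.counts_json())
            outputs.append(path)

        # --- pathway enrichment (all / up-only / down-only) ------------------
        stage = "enrichment"
        if cfg.pathways:
            for tissue in cfg.tissues:
                res = de_results[tissue]
                universe = set(map(str, res.records.index))
                coll = PathwayCollection.from_gmt(cfg.pathways, universe=universe)
                up, down = set(map(str, res.up)), set(map(str, res.down))
                sig = up | down
                if not sig:
                    continue
                kw = {"min_members": cfg.enrichment_min_members, "p_threshold": cfg.enrichment_p}
                records = hypergeometric_enrichment(sig, coll, **kw)
                up_rec = hypergeometric_enrichment(up, coll, **kw) if up else records.iloc[0:0]
                down_rec = hypergeometric_enrichment(down, coll, **kw) if down else records.iloc[0:0]
                classes = bimodal_classification(up_rec, down_rec)
                records["polarity_score"] = [
                    polarity_score(coll.pathways[pid], up, down) for pid in records.index
                ]
                records["class"] = classes.reindex(records.index).fillna("none")
                path = outdir / f"enrichment_{_slug(tissue)}.tsv"
                records.to_csv(path, sep="\t")
                outputs.append(path)

        # --- iTRAQ protein quantification ------------------------------------
        stage = "itraq"
        protein_set = None
        if cfg.peptides:
            table = read_peptide_table(cfg.peptides)
            quant = ReporterQuant(table, min_peptides=cfg.min_peptides).fit(
                lo=cfg.itraq_lo, hi=cfg.itraq_hi, channel_mode=cfg.channel_mode
            )
            path = outdir / "protein_calls.tsv"
            quant.to_tsv(path)
            outputs.append(path)
            path = outdir / "itraq_qc.json"
            path.write_text(json.dumps(quant.qc_report(), indent=2))
            outputs.append(path)
            protein_set = quant.signed_set("protein")

        # --- cross-omics overlap ----------------------------------------------
        stage = "cross_omics"
        if protein_set is not None and cfg.tissues:
            transcripts = signed_sets[cfg.tissues[0]]
            transcripts.label = "transcript"
            _, concordance = cross_omics_overlap(transcripts, protein_set)
            path = outdir / "cross_omics.tsv"
            concordance.to_csv(path, sep="\t", index=False)
            outputs.append(path)

        # --- latent semantic literature scoring --------------------------------
        stage = "semantics"
        if cfg.corpus and cfg.queries:
            corpus = Corpus.from_jsonl(cfg.corpus)
            lsi = LsiModel(corpus, k=cfg.lsi_k).fit()
            for query in cfg.queries:
                scores = lsi.keyword_gene_scores(query)
                path = outdir / f"semantics_{_slug(query)}.tsv"
                scores.to_csv(path, sep="\t", index=False)
                outputs.append(path)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": cfg.seed,
            "thresholds": {
                "zr_threshold": cfg.zr_threshold,
                "p_threshold": cfg.p_threshold,
                "fdr_threshold": cfg.fdr_threshold,
                "itraq_lo": cfg.itraq_lo,
                "itraq_hi": cfg.itraq_hi,
                "enrichment_min_members": cfg.enrichment_min_members,
                "enrichment_p": cfg.enrichment_p,
            },
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    partial_marker.unlink(missing_ok=True)
    return manifest


def demo(output_dir, seed: int = 0, n_genes: int = 400) -> dict:
    """Generate a synthetic two-tissue study and run the full analysis on it.

    The planted differential proteins are drawn from the hippocampal
    planted up-regulated transcripts, so true signals propagate into the
    cross-omics concordant overlap.
    """
    outdir = Path(output_dir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    expression = {}
    truths = {}
    for tissue in ("hippocampus", "cortex"):
        control, case, truth = simulate_expression_study(
            n_genes=n_genes, n_replicates=3, de_fraction=0.05, effect=3.0, seed=sub(), tissue=tissue
        )
        cpath = inputs / f"{tissue}_control.tsv"
        kpath = inputs / f"{tissue}_case.tsv"
        control.to_tsv(cpath)
        case.to_tsv(kpath)
        expression[tissue] = {"control": str(cpath), "case": str(kpath)}
        truths[tissue] = truth

    genes = [f"g{i:0{len(str(n_genes))}d}" for i in range(1, n_genes + 1)]
    hip_truth = truths["hippocampus"]
    planted_up = sorted(g for g, (pol, _) in hip_truth.de_genes.items() if pol > 0)
    protein_ids = sorted(set(planted_up[:5]) | set(genes[: n_genes // 4]))
    peptides, itraq_truth = simulate_itraq_experiment(
        peptides_per_protein=3,
        control_cv=0.05,
        fold=1.5,
        seed=sub(),
        protein_ids=protein_ids,
        planted=planted_up[:5],
    )
    pep_path = inputs / "peptides.csv"
    peptides.to_csv(pep_path, index=False)

    de_union = sorted(set(hip_truth.de_genes) | set(truths["cortex"].de_genes))
    coll, pw_truth = simulate_pathway_annotation(
        n_pathways=15,
        universe=genes,
        planted={"pw01", "pw02"},
        de_genes=de_union,
        enrichment_factor=5.0,
        seed=sub(),
    )
    gmt_path = inputs / "pathways.gmt"
    coll.to_gmt(gmt_path)

    keywords = ["autism", "obsessive"]
    links = {(g, "autism"): "explicit" for g in planted_up[:3]}
    links.update({(g, "obsessive"): "implicit" for g in planted_up[3:5]})
    corpus_genes = list(dict.fromkeys(genes[:50] + planted_up[:5]))
    corpus, corpus_truth = simulate_literature_corpus(corpus_genes, keywords, links, seed=sub())
    corpus_path = inputs / "corpus.jsonl"
    corpus.to_jsonl(corpus_path)

    truth_path = inputs / "truth.json"
    combined = {
        "seed": seed,
        "de_genes": {t: {g: list(v) for g, v in truths[t].de_genes.items()} for t in truths},
        "diff_proteins": itraq_truth.diff_proteins,
        "enriched_pathways": sorted(pw_truth.enriched_pathways),
        "keyword_links": {f"{g}|{k}": v for (g, k), v in corpus_truth.keyword_links.items()},
    }
    truth_path.write_text(json.dumps(combined, indent=2))

    cfg = AnalysisConfig(
        output_dir=str(outdir / "results"),
        tissues=["hippocampus", "cortex"],
        expression=expression,
        peptides=str(pep_path),
        pathways=str(gmt_path),
        corpus=str(corpus_path),
        queries=keywords,
        seed=seed,
        lsi_k=20,
    )
    cfg.to_yaml(outdir / "demo_config.yaml")
    return run_full_analysis(cfg)
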