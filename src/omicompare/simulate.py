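"""Synthetic inputs with planted ground truth for every analysis stage.

Four generators emulate the data shapes of a two-genotype mouse brain
study — case (BTBR-like) vs. control (B6-like):

* :func:`simulate_expression_study` — per-genotype microarray intensity
  matrices (log10-normal, gene-specific baselines) with a chosen fraction
  of genes shifted up or down by a stated number of standardized
  log-intensity units;
* :func:`simulate_itraq_experiment` — a 4-plex peptide reporter-ion table
  with pooled controls in channels 114/115 and cases in 116/117,
  log-normal channel noise at a stated CV, and planted fold changes;
* :func:`simulate_pathway_annotation` — a gene-set collection in which
  chosen pathways over-sample a differential gene list by a stated factor;
* :func:`simulate_literature_corpus` — gene documents with planted
  explicit (keyword present) and implicit (shared context vocabulary
  only) keyword associations over otherwise orthogonal vocabularies.

Each generator records its planted truth in a :class:`SimulationTruth`
and is fully determined by its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import PathwayCollection
from .microarray_de import IntensityMatrix
from .semantics import Corpus

__all__ = [
    "SimulationTruth",
    "simulate_expression_study",
    "simulate_itraq_experiment",
    "simulate_pathway_annotation",
    "simulate_literature_corpus",
]

# default log10-intensity model: between-gene baseline spread dominates
# the per-array replicate noise, as on a typical expression array
BASELINE_MEAN = 2.5  # mean log10 intensity (~300 a.u.)
BASELINE_SD = 1.0  # between-gene spread, log10 units
NOISE_SD = 0.3  # between-animal biological replicate noise, log10 units (~2-fold SD)


@dataclass
class SimulationTruth:
    """Planted signals of a synthetic dataset, keyed by the generating seed."""

    seed: int
    de_genes: dict[str, tuple[int, float]] = field(default_factory=dict)
    diff_proteins: dict[str, float] = field(default_factory=dict)
    enriched_pathways: set[str] = field(default_factory=set)
    keyword_links: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "de_genes": {g: list(v) for g, v in self.de_genes.items()},
            "diff_proteins": self.diff_proteins,
            "enriched_pathways": sorted(self.enriched_pathways),
            "keyword_links": {f"{g}|{k}": v for (g, k), v in self.keyword_links.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_expression_study(
    n_genes: int = 1000,
    n_replicates: int = 3,
    de_fraction: float = 0.05,
    effect: float = 3.0,
    seed: int = 0,
    baseline_mean: float = BASELINE_MEAN,
    baseline_sd: float = BASELINE_SD,
    noise_sd: float = NOISE_SD,
    tissue: str = "tissue",
) -> tuple[IntensityMatrix, IntensityMatrix, SimulationTruth]:
    """Two-group microarray study with planted signed differential genes.

    Gene g on array s has log10 intensity ``b_g + eps_{gs}`` with
    ``b_g ~ N(baseline_mean, baseline_sd)`` and
    ``eps ~ N(0, noise_sd)``; case arrays add the planted shift
    ``polarity * effect * sqrt(baseline_sd^2 + noise_sd^2)`` — i.e.
    ``effect`` is expressed in standardized (per-array z) log-intensity
    units.  ``round(n_genes * de_fraction)`` genes are planted, half up /
    half down (odd counts favour up).

    Returns ``(control, case, truth)``.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if not 0 <= de_fraction < 1:
        raise ValueError("de_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]

    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    n_de = round(n_genes * de_fraction)
    n_up = (n_de + 1) // 2  # ties to up
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    polarity = np.zeros(n_genes)
    polarity[de_idx[:n_up]] = +1
    polarity[de_idx[n_up:]] = -1
    shift = polarity * effect * np.hypot(baseline_sd, noise_sd)

    def arrays(group: str, shifted: bool) -> pd.DataFrame:
        cols = {}
        for r in range(1, n_replicates + 1):
            eps = rng.normal(0.0, noise_sd, size=n_genes)
            logi = baselines + eps + (shift if shifted else 0.0)
            cols[f"{tissue}_{group}_{r}"] = 10.0 ** logi
        return pd.DataFrame(cols, index=genes)

    def matrix(group: str, shifted: bool) -> IntensityMatrix:
        values = arrays(group, shifted)
        meta = pd.DataFrame(
            {
                "genotype": group,
                "tissue": tissue,
                "replicate": range(1, n_replicates + 1),
            },
            index=values.columns,
        )
        return IntensityMatrix(values=values, sample_meta=meta)

    control = matrix("control", shifted=False)
    case = matrix("case", shifted=True)
    truth = SimulationTruth(
        seed=seed,
        de_genes={genes[i]: (int(polarity[i]), float(effect)) for i in de_idx},
    )
    return control, case, truth


def simulate_itraq_experiment(
    n_proteins: int = 500,
    peptides_per_protein: int = 3,
    control_cv: float = 0.05,
    diff_fraction: float = 0.1,
    fold: float = 1.5,
    seed: int = 0,
    protein_ids=None,
    planted=None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """4-plex peptide reporter table with planted case/control fold changes.

    Channels 114/115 (pooled controls) scatter around a common per-peptide
    abundance with multiplicative log-normal noise of coefficient of
    variation ``control_cv``; channels 116/117 do the same times ``fold``
    for the planted fraction of proteins.  ``control_cv=0`` produces exact
    unit ratios.  ``protein_ids`` overrides the generated accession names
    and ``planted`` pins the differential proteins (instead of a random
    ``diff_fraction`` draw), which lets callers align protein identities
    with a simulated transcriptome.
    """
    if peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not 0 <= diff_fraction < 1:
        raise ValueError("diff_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if protein_ids is not None:
        proteins = list(protein_ids)
        n_proteins = len(proteins)
    else:
        if n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        width = len(str(n_proteins))
        proteins = [f"P{i:0{width}d}" for i in range(1, n_proteins + 1)]
    if planted is not None:
        unknown = set(planted) - set(proteins)
        if unknown:
            raise ValueError(f"planted proteins not in protein ids: {sorted(unknown)}")
        diff_idx = {proteins.index(p) for p in planted}
    else:
        n_diff = round(n_proteins * diff_fraction)
        diff_idx = set(rng.choice(n_proteins, size=n_diff, replace=False).tolist())

    sigma = np.sqrt(np.log1p(control_cv**2))  # log-normal sigma for the stated CV
    rows = []
    for i, pid in enumerate(proteins):
        abundance = 10.0 ** rng.normal(4.0, 0.5)
        pfold = fold if i in diff_idx else 1.0
        for j in range(1, peptides_per_protein + 1):
            base = abundance * 10.0 ** rng.normal(0.0, 0.2)  # peptide ionization efficiency
            noise = np.exp(rng.normal(0.0, sigma, size=4)) if sigma > 0 else np.ones(4)
            rows.append(
                {
                    "peptide_id": f"{pid}_pep{j}",
                    "protein_id": pid,
                    "i114": base * noise[0],
                    "i115": base * noise[1],
                    "i116": base * pfold * noise[2],
                    "i117": base * pfold * noise[3],
                }
            )
    table = pd.DataFrame(rows, columns=["peptide_id", "protein_id", "i114", "i115", "i116", "i117"])
    truth = SimulationTruth(seed=seed, diff_proteins={proteins[i]: float(fold) for i in sorted(diff_idx)})
    return table, truth


def simulate_pathway_annotation(
    n_pathways: int,
    universe,
    planted,
    de_genes,
    enrichment_factor: float = 5.0,
    seed: int = 0,
    size_range: tuple[int, int] = (10, 40),
) -> tuple[PathwayCollection, SimulationTruth]:
    """Gene-set collection in which planted pathways over-sample DE genes.

    Non-planted pathways draw members uniformly from the universe
    (hypergeometric null); planted pathways include DE genes at
    ``enrichment_factor`` times the background rate ``|de|/|universe|``
    (capped at 1), filling the rest from non-DE genes.
    """
    universe = sorted(set(universe))
    de = sorted(set(de_genes) & set(universe))
    non_de = sorted(set(universe) - set(de))
    if not universe:
        raise ValueError("universe must be non-empty")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be > 0")
    ids = [f"pw{i:02d}" for i in range(1, n_pathways + 1)]
    planted = set(planted)
    if not planted <= set(ids):
        raise ValueError(f"planted ids not among generated pathway ids {ids[0]}..{ids[-1]}")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    base_rate = len(de) / len(universe)
    pathways = {}
    for pid in ids:
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        if pid in planted and de:
            rate = min(1.0, enrichment_factor * base_rate)
            n_from_de = min(len(de), int(round(rate * size)))
            members = set(rng.choice(de, size=n_from_de, replace=False))
            rest = min(size - n_from_de, len(non_de))
            members |= set(rng.choice(non_de, size=rest, replace=False))
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
        pathways[pid] = members
    coll = PathwayCollection(pathways, universe)
    truth = SimulationTruth(seed=seed, enriched_pathways=set(planted))
    return coll, truth


def simulate_literature_corpus(
    genes,
    keywords,
    links: dict[tuple[str, str], str],
    seed: int = 0,
    filler_words_per_gene: int = 8,
    filler_repeats: int = 3,
    context_words_per_keyword: int = 5,
    background_docs_per_keyword: int = 4,
) -> tuple[Corpus, SimulationTruth]:
    """Toy gene-literature corpus with planted keyword associations.

    Every gene document carries its own private filler vocabulary, so
    unlinked genes share no terms with any keyword context.  An
    ``explicit`` link puts the keyword itself (plus the keyword's context
    vocabulary) into the gene's document; an ``implicit`` link puts only
    the context vocabulary.  For every keyword that participates in a
    link, ``background_docs_per_keyword`` extra literature documents
    (ids ``lit_<keyword>_<i>``, not genes) co-mention the keyword with its
    context vocabulary — these play the role of the abstract corpus that
    lets latent indexing tie context terms to the keyword, so implicit
    links are recoverable only through the reduced-rank space.
    """
    genes = list(genes)
    keywords = list(keywords)
    for (g, k), kind in links.items():
        if g not in genes:
            raise ValueError(f"link references unknown gene {g!r}")
        if k not in keywords:
            raise ValueError(f"link references unknown keyword {k!r}")
        if kind not in ("explicit", "implicit"):
            raise ValueError(f"link kind must be explicit/implicit, got {kind!r}")
    rng = np.random.default_rng(seed)
    context = {
        k: [f"{k}ctx{i}" for i in range(1, context_words_per_keyword + 1)] for k in keywords
    }

    def shuffled(tokens: list[str]) -> str:
        order = rng.permutation(len(tokens))
        return " ".join(tokens[i] for i in order)

    documents = {}
    for g in genes:
        tokens = []
        for i in range(1, filler_words_per_gene + 1):
            tokens.extend([f"{g}w{i}"] * filler_repeats)
        for k in keywords:
            kind = links.get((g, k))
            if kind == "explicit":
                tokens.extend([k] * 6)
                tokens.extend(context[k] * 2)
            elif kind == "implicit":
                tokens.extend(context[k] * 2)
        documents[g] = shuffled(tokens)
    linked_keywords = [k for k in keywords if any(kk == k for (_, kk) in links)]
    for k in linked_keywords:
        for b in range(1, background_docs_per_keyword + 1):
            tokens = [k] * 3 + context[k] * 3
            for i in range(1, 4):
                tokens.extend([f"lit{k}{b}w{i}"] * 2)
            documents[f"lit_{k}_{b}"] = shuffled(tokens)
    corpus = Corpus(documents=documents)
    truth = SimulationTruth(seed=seed, keyword_links=dict(links))
    return corpus, truth
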