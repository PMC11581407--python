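"""Planted-truth generators for every input the pipeline consumes.

The generators emulate the focal analysis's stated world: a transcript
universe of 10,903 detected features with 3.5% increased and 1.6% decreased
abundance, marker studies whose members are increased at a planted
fold-enrichment rho over background, a many-to-many gene-to-protein-isoform
map with an 8.58% increased protein universe, a cell-type marker database
with one planted enriched term, and immunoblot replicate fixtures with a
known fold change.  Everything is reproducible from one master seed; each
component draws from its own derived stream so regenerating one file never
perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .de_table import DEDataset
from .marker_lists import MarkerList, SelectionRule, finalize_against
from .quant import QuantGroup

_ALPHA = 0.05  # significance level the planted adj-p columns encode


def _rng(seed: int, component: str) -> np.random.Generator:
    """Independent per-component stream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(component.encode())])


@dataclass(frozen=True)
class ListSpec:
    """One marker list to plant: its size, enrichment rho, and construction."""

    name: str
    size: int
    rho: float
    combination: str = "single"  # single | union | intersection
    rule: SelectionRule = field(default_factory=lambda: SelectionRule("log2fc", 0.5, 0.05))


#: the battery implied by the published immune-challenge comparison table:
#: detected sizes and the fold enrichments implied by its printed counts.
DEFAULT_LISTS = (
    ListSpec("immune_meta", 55, 14.65, "single", SelectionRule("all")),
    ListSpec("bacteria", 159, 9.77, "single", SelectionRule("log2fc", 1.0, 0.05)),
    ListSpec("viruses", 36, 12.79, "single", SelectionRule("log2fc", 0.5, 0.05)),
    ListSpec("fungi", 132, 8.72, "union", SelectionRule("fc", 1.5, None)),
    ListSpec("parasitoids", 31, 19.49, "intersection", SelectionRule("log2fc", 0.5, 0.05)),
)


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic bundle."""

    n_features: int = 10903
    frac_up: float = 0.035
    frac_down: float = 0.016
    per_list: tuple = DEFAULT_LISTS
    isoform_lambda: float = 1.5
    protein_frac_up: float = 0.0858
    protein_frac_down: float = 0.04
    protein_detect_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_up and 0 <= self.frac_down and self.frac_up + self.frac_down <= 1):
            raise ValueError("frac_up/frac_down must be nonnegative and sum to <= 1")
        for spec in self.per_list:
            if spec.rho < 0:
                raise ValueError(f"{spec.name}: rho must be >= 0")
            if spec.rho * self.frac_up > 1:
                raise ValueError(f"{spec.name}: rho * frac_up exceeds 1")
            if spec.size > self.n_features:
                raise ValueError(f"{spec.name}: list larger than the universe")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        lists = cfg.pop("lists", None)
        truth = cls(**cfg) if lists is None else cls(
            per_list=tuple(
                ListSpec(
                    name=e["name"], size=e["size"], rho=e["rho"],
                    combination=e.get("combination", "single"),
                    rule=SelectionRule(
                        e.get("statistic", "log2fc"),
                        e.get("threshold", 0.5 if e.get("statistic", "log2fc") != "all" else None),
                        e.get("adj_p_max"),
                    ),
                )
                for e in lists
            ),
            **cfg,
        )
        return truth


# ---------------------------------------------------------------------------
# universes
# ---------------------------------------------------------------------------

def _stats_for_directions(direction: np.ndarray, rng: np.random.Generator):
    """adj-p and log2fc columns consistent with planted direction flags at
    alpha = 0.05: calling directions on the generated table recovers the
    planted flags exactly."""
    n = direction.size
    up = direction == "increased"
    down = direction == "decreased"
    flat = ~(up | down)
    adj = np.empty(n)
    adj[up | down] = rng.uniform(0.0, _ALPHA, (up | down).sum())
    adj[flat] = rng.uniform(_ALPHA + 1e-6, 1.0, flat.sum())
    lfc = np.empty(n)
    lfc[up] = 0.5 + rng.exponential(1.0, up.sum())
    lfc[down] = -(0.5 + rng.exponential(1.0, down.sum()))
    lfc[flat] = rng.normal(0.0, 0.4, flat.sum())
    p = adj * rng.uniform(0.05, 1.0, n)
    return lfc, p, adj


def generate_universe(truth: SyntheticTruth, modality: str = "transcript") -> DEDataset:
    """Draw the focal detected universe with planted direction fractions."""
    rng = _rng(truth.seed, "universe")
    n = truth.n_features
    u = rng.random(n)
    direction = np.where(
        u < truth.frac_up, "increased",
        np.where(u < truth.frac_up + truth.frac_down, "decreased", "unchanged"),
    )
    lfc, p, adj = _stats_for_directions(direction, rng)
    feature_ids = [f"FBtr{3000000 + i:07d}" for i in range(n)]
    gene_ids = [f"FBgn{1000000 + i:07d}" for i in range(n)]
    table = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": p, "adj_pvalue": adj,
         "direction": direction},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return DEDataset(modality=modality, table=table)


def universe_from_counts(
    n_detected: int, n_increased: int, n_decreased: int = 0,
    modality: str = "transcript",
) -> DEDataset:
    """Deterministic universe with exact direction counts.

    Used to rebuild published universes from their printed summary counts
    (e.g. 10,903 detected / 379 increased / 175 decreased): the identities of
    the features are immaterial to any overlap statistic, only the counts
    enter the 2x2 table.
    """
    if n_increased + n_decreased > n_detected:
        raise ValueError("direction counts exceed the detected total")
    direction = np.array(
        ["increased"] * n_increased + ["decreased"] * n_decreased
        + ["unchanged"] * (n_detected - n_increased - n_decreased)
    )
    lfc = np.where(direction == "increased", 2.0, np.where(direction == "decreased", -2.0, 0.0))
    adj = np.where(direction == "unchanged", 1.0, 0.001)
    prefix = "FBtr" if modality == "transcript" else "FBpp"
    feature_ids = [f"{prefix}{5000000 + i:07d}" for i in range(n_detected)]
    gene_ids = [f"FBgn{5000000 + i:07d}" for i in range(n_detected)]
    table = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": adj * 0.5, "adj_pvalue": adj,
         "direction": direction},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return DEDataset(modality=modality, table=table)


def marker_list_from_counts(
    universe: DEDataset, n_detected: int, n_overlap: int, name: str
) -> MarkerList:
    """Deterministic finalized list with exact detected/overlap counts,
    drawn from a :func:`universe_from_counts` universe."""
    inc = sorted(universe.direction_keys("increased"))
    other = sorted(universe.detected_keys() - universe.direction_keys("increased"))
    if n_overlap > len(inc) or n_detected - n_overlap > len(other):
        raise ValueError("requested counts exceed the universe's direction classes")
    members = inc[:n_overlap] + other[: n_detected - n_overlap]
    return finalize_against(members, universe, name=name)


# ---------------------------------------------------------------------------
# marker studies
# ---------------------------------------------------------------------------

def plant_membership(
    universe: DEDataset, size: int, rho: float, rng: np.random.Generator,
    frac_up: float | None = None,
) -> frozenset[str]:
    """Sample a gene set in which each member is increased in the universe
    with probability min(1, rho * frac_up)."""
    frac_up = (
        frac_up if frac_up is not None
        else universe.n_increased / universe.n_detected
    )
    q = min(1.0, rho * frac_up)
    inc = np.array(sorted(universe.direction_keys("increased")))
    rest = np.array(sorted(universe.detected_keys() - set(inc)))
    n_up = int(rng.binomial(size, q))
    n_up = min(n_up, len(inc), size)
    n_other = min(size - n_up, len(rest))
    members = np.concatenate([
        rng.choice(inc, n_up, replace=False),
        rng.choice(rest, n_other, replace=False),
    ])
    return frozenset(members.tolist())


def _passing_stats(rule: SelectionRule, n: int, rng) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    if rule.statistic == "all":
        cols["log2fc"] = rng.normal(1.0, 0.5, n)
    elif rule.statistic == "empai":
        cols["empai"] = rule.threshold + rng.exponential(1.0, n) + 1e-9
    else:
        cols[rule.statistic] = rule.threshold + rng.exponential(0.5, n)
    if rule.adj_p_max is not None:
        cols["adj_pvalue"] = rng.uniform(0.0, rule.adj_p_max, n)
    return cols


def _failing_stats(rule: SelectionRule, n: int, rng) -> dict[str, np.ndarray]:
    # decoys fail on the statistic itself, so they fail regardless of adj-p
    cols: dict[str, np.ndarray] = {}
    if rule.statistic == "empai":
        cols["empai"] = rng.uniform(0.05, 1.0, n)
    else:
        t = rule.threshold
        cols[rule.statistic] = rng.uniform(min(0.0, t - 1.0), t - 1e-6, n)
    if rule.adj_p_max is not None:
        cols["adj_pvalue"] = rng.uniform(0.0, 1.0, n)
    return cols


def _study_frame(genes, stats: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame({"gene_id": list(genes), **stats})


def generate_marker_study(truth: SyntheticTruth, spec: ListSpec, universe: DEDataset):
    """Generate the study table(s) behind one planted marker list.

    Returns ``(studies, entry)`` where ``studies`` is a list of
    ``(study_id, DataFrame, SelectionRule)`` and ``entry`` records the planted
    truth: raw members (including a handful of not-detected genes, so the
    detection filter has work to do), detected members, and rho.  The tables
    are built so that applying each study's selection rule and the list's
    combination mode recovers the raw member set exactly.
    """
    rng = _rng(truth.seed, f"study:{spec.name}")
    members = plant_membership(universe, spec.size, spec.rho, rng, frac_up=truth.frac_up)

    n_undet = max(1, spec.size // 10)
    undetected = [f"FBgn{8000000 + zlib.crc32(spec.name.encode()) % 100000 + i:07d}"
                  for i in range(n_undet)]
    raw = frozenset(members) | frozenset(undetected)
    pool = sorted(universe.gene_ids() - members)
    rule = spec.rule

    def passing(genes):
        return _study_frame(genes, _passing_stats(rule, len(genes), rng))

    def failing(genes):
        return _study_frame(genes, _failing_stats(rule, len(genes), rng))

    raw_sorted = sorted(raw)
    studies = []
    if spec.combination == "single":
        frame = passing(raw_sorted)
        if rule.statistic != "all":  # 'all' admits no failing rows
            decoys = rng.choice(pool, min(spec.size, len(pool)), replace=False)
            frame = pd.concat([frame, failing(decoys)], ignore_index=True)
        studies.append((f"{spec.name}_s1", frame, rule))
    elif spec.combination == "union":
        # two studies covering overlapping 60% slices; union = raw exactly
        cut = len(raw_sorted)
        a = raw_sorted[: int(np.ceil(cut * 0.6))]
        b = raw_sorted[int(np.floor(cut * 0.4)):]
        for sid, part in (("s1", a), ("s2", b)):
            frame = passing(part)
            if rule.statistic != "all":
                decoys = rng.choice(pool, min(len(part), len(pool)), replace=False)
                frame = pd.concat([frame, failing(decoys)], ignore_index=True)
            studies.append((f"{spec.name}_{sid}", frame, rule))
    elif spec.combination == "intersection":
        # both studies pass all members; each adds disjoint extra passers,
        # so the intersection strips them back off
        extra = rng.choice(pool, min(2 * n_undet, len(pool)), replace=False)
        half = len(extra) // 2
        for sid, ex in (("s1", extra[:half]), ("s2", extra[half:])):
            frame = passing(raw_sorted + sorted(ex))
            studies.append((f"{spec.name}_{sid}", frame, rule))
    else:
        raise ValueError(f"unknown combination {spec.combination!r}")

    entry = {
        "name": spec.name,
        "combination": spec.combination,
        "rho": spec.rho,
        "raw_members": sorted(raw),
        "detected_members": sorted(members),
    }
    return studies, entry


# ---------------------------------------------------------------------------
# identifier map and protein universe
# ---------------------------------------------------------------------------

def generate_idmap(truth: SyntheticTruth, universe: DEDataset):
    """Many-to-many gene -> protein-isoform map plus a protein universe.

    Each gene receives 1 + Poisson(isoform_lambda - 1) isoforms; each isoform
    is detected in the protein universe with probability
    ``protein_detect_rate`` and, if detected, increased with probability
    ``protein_frac_up`` (decreased with ``protein_frac_down``).
    """
    if truth.isoform_lambda < 1:
        raise ValueError("isoform_lambda must be >= 1")
    rng = _rng(truth.seed, "idmap")
    genes = sorted(universe.gene_ids())
    counts = 1 + rng.poisson(truth.isoform_lambda - 1.0, len(genes))

    gene_to_proteins: dict[str, frozenset[str]] = {}
    rows_gene, rows_prot = [], []
    pid = 0
    for gene, k in zip(genes, counts):
        prots = [f"FBpp{700000 + pid + j:07d}" for j in range(int(k))]
        pid += int(k)
        gene_to_proteins[gene] = frozenset(prots)
        rows_gene.extend([gene] * int(k))
        rows_prot.extend(prots)

    transcript_to_gene = dict(zip(universe.table.index, universe.table["gene_id"]))

    from .marker_lists import IdMap

    idmap = IdMap(gene_to_proteins=gene_to_proteins, transcript_to_gene=transcript_to_gene)

    detected = np.asarray(rng.random(len(rows_prot)) < truth.protein_detect_rate)
    if not detected.any():
        detected[0] = True
    det_prots = [p for p, keep in zip(rows_prot, detected) if keep]
    det_genes = [g for g, keep in zip(rows_gene, detected) if keep]
    u = rng.random(len(det_prots))
    direction = np.where(
        u < truth.protein_frac_up, "increased",
        np.where(u < truth.protein_frac_up + truth.protein_frac_down, "decreased", "unchanged"),
    )
    lfc, p, adj = _stats_for_directions(direction, rng)
    table = pd.DataFrame(
        {"gene_id": det_genes, "log2fc": lfc, "pvalue": p, "adj_pvalue": adj,
         "direction": direction},
        index=pd.Index(det_prots, name="feature_id"),
    )
    protein_universe = DEDataset(modality="protein", table=table)
    return idmap, protein_universe


# ---------------------------------------------------------------------------
# cell-type marker database
# ---------------------------------------------------------------------------

def generate_celltype_db(
    universe_genes,
    query_genes,
    n_terms: int = 10,
    markers_per_term: int = 40,
    planted_term: str = "activated_macrophage",
    planted_query_frac: float = 0.5,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Marker database with one term planted to overlap the query list.

    The planted term draws ``planted_query_frac`` of its markers from the
    query; the other terms draw uniformly from the universe.
    """
    rng = _rng(seed, "celltypedb")
    universe_genes = np.array(sorted(set(universe_genes)))
    query = np.array(sorted(set(query_genes)))
    rest = np.array(sorted(set(universe_genes) - set(query)))

    db: dict[str, frozenset[str]] = {}
    k = min(int(round(markers_per_term * planted_query_frac)), len(query))
    planted = np.concatenate([
        rng.choice(query, k, replace=False),
        rng.choice(rest, markers_per_term - k, replace=False),
    ])
    db[planted_term] = frozenset(planted.tolist())
    for i in range(n_terms - 1):
        db[f"celltype_{i:02d}"] = frozenset(
            rng.choice(universe_genes, markers_per_term, replace=False).tolist()
        )
    return db


# ---------------------------------------------------------------------------
# immunoblot fixtures
# ---------------------------------------------------------------------------

def generate_quant_groups(
    seed: int = 0, n: int = 4, true_fold: float = 2.0, noise_cv: float = 0.10
) -> tuple[QuantGroup, QuantGroup]:
    """Replicate densitometry fixtures with lognormal noise of known CV."""
    rng = _rng(seed, "quant")
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    ref_e = rng.uniform(0.8, 1.2, n)
    ref_c = rng.uniform(0.8, 1.2, n)
    exp = QuantGroup("experimental", true_fold * ref_e * rng.lognormal(0.0, sigma, n), ref_e)
    ctl = QuantGroup("control", ref_c * rng.lognormal(0.0, sigma, n), ref_c)
    return exp, ctl


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

def write_bundle(truth: SyntheticTruth, outdir) -> dict:
    """Emit every pipeline input as files plus a truth.json, and return the
    paths.  Layout: universe.tsv, proteins.tsv, idmap_gene_protein.tsv,
    idmap_transcript_gene.tsv, studies/*.tsv, lists.yaml, truth.json."""
    outdir = Path(outdir)
    (outdir / "studies").mkdir(parents=True, exist_ok=True)

    universe = generate_universe(truth)
    de_path = outdir / "universe.tsv"
    universe.to_tsv(de_path)

    idmap, protein_universe = generate_idmap(truth, universe)
    prot_path = outdir / "proteins.tsv"
    protein_universe.to_tsv(prot_path)
    gp_path = outdir / "idmap_gene_protein.tsv"
    with open(gp_path, "w") as fh:
        fh.write("gene_id\tprotein_id\n")
        for gene in sorted(idmap.gene_to_proteins):
            for prot in sorted(idmap.gene_to_proteins[gene]):
                fh.write(f"{gene}\t{prot}\n")
    tg_path = outdir / "idmap_transcript_gene.tsv"
    with open(tg_path, "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for t, g in idmap.transcript_to_gene.items():
            fh.write(f"{t}\t{g}\n")

    config: dict = {"lists": []}
    truth_lists = []
    for spec in truth.per_list:
        studies, entry = generate_marker_study(truth, spec, universe)
        blocks = []
        for study_id, frame, rule in studies:
            fname = f"studies/{study_id}.tsv"
            frame.to_csv(outdir / fname, sep="\t", index=False)
            blocks.append({
                "id": study_id,
                "file": fname,
                "rule": {
                    "statistic": rule.statistic,
                    **({"threshold": rule.threshold} if rule.threshold is not None else {}),
                    **({"adj_p_max": rule.adj_p_max} if rule.adj_p_max is not None else {}),
                },
            })
        config["lists"].append(
            {"name": spec.name, "combination": spec.combination, "studies": blocks}
        )
        truth_lists.append(entry)

    lists_path = outdir / "lists.yaml"
    with open(lists_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "n_features": truth.n_features,
                "frac_up": truth.frac_up,
                "frac_down": truth.frac_down,
                "protein_frac_up": truth.protein_frac_up,
                "isoform_lambda": truth.isoform_lambda,
                "seed": truth.seed,
                "lists": truth_lists,
            },
            fh, indent=2,
        )

    return {
        "universe": de_path, "proteins": prot_path,
        "idmap_gene_protein": gp_path, "idmap_transcript_gene": tg_path,
        "lists_config": lists_path, "truth": truth_path,
    }
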