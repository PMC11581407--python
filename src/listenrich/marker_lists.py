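"""Compile marker gene lists from published-study tables.

A *marker list* is the set of genes a published study found significantly
induced by an immune challenge (or enriched in an immune-cell subtype).  Each
source study ships its own table and its own selection cutoff — a fold-change
threshold, a log2 fold-change threshold, an emPAI abundance cutoff, or simply
"take every gene".  Lists built from two related studies are combined by set
union or intersection.  Before any overlap statistic, a list is *finalized*
against the focal detected universe: members not detected there are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .de_table import DEDataset

logger = logging.getLogger(__name__)

STATISTICS = ("log2fc", "fc", "empai", "all")
COMBINATIONS = ("single", "union", "intersection")


@dataclass(frozen=True)
class SelectionRule:
    """A study's marker-selection cutoff.

    ``statistic`` names the column the threshold applies to. Fold-change and
    log2 fold-change thresholds are inclusive (``>=``), the emPAI cutoff is
    strict (``>``), and the adjusted-p cutoff is inclusive (``<=``) — matching
    how source studies print them.  ``statistic="all"`` takes every gene in
    the table and admits no thresholds.
    """

    statistic: str = "all"
    threshold: float | None = None
    adj_p_max: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.statistic == "all":
            if self.threshold is not None or self.adj_p_max is not None:
                raise ValueError("rule 'all' admits no thresholds")
        elif self.threshold is None:
            raise ValueError(f"rule on {self.statistic!r} requires a threshold")

    @property
    def strict(self) -> bool:
        return self.statistic == "empai"


@dataclass
class MarkerStudy:
    """One published study's table plus its selection rule."""

    study_id: str
    table: pd.DataFrame
    rule: SelectionRule
    source_accession: str = ""


@dataclass(frozen=True)
class MarkerList:
    """A named, combined, optionally detection-filtered gene set."""

    name: str
    combination: str
    raw_members: frozenset[str]
    detected_members: frozenset[str] = frozenset()
    modality: str = "transcript"

    def __post_init__(self) -> None:
        if self.combination not in COMBINATIONS:
            raise ValueError(f"unknown combination {self.combination!r}")
        if not self.detected_members <= self.raw_members:
            raise ValueError(f"{self.name}: detected members not a subset of raw members")

    @property
    def n_raw(self) -> int:
        return len(self.raw_members)

    @property
    def n_detected(self) -> int:
        return len(self.detected_members)


@dataclass
class IdMap:
    """Transcript -> gene and gene -> protein-isoform identifier map.

    Gene-to-protein is many-to-many capable (a gene may encode several
    isoforms).  Lookups of unmapped ids return the empty set, never an error.
    """

    gene_to_proteins: dict[str, frozenset[str]] = field(default_factory=dict)
    transcript_to_gene: dict[str, str] = field(default_factory=dict)

    def proteins_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_proteins.get(gene_id, frozenset())

    def gene_of(self, transcript_id: str) -> str | None:
        return self.transcript_to_gene.get(transcript_id)

    @classmethod
    def from_tsv(cls, gene_protein_path, transcript_gene_path=None) -> "IdMap":
        """Read pair files: (gene_id, protein_id) and optionally
        (transcript_id, gene_id), one pair per row, with header."""
        g2p: dict[str, set[str]] = {}
        gp = pd.read_csv(gene_protein_path, sep="\t", dtype=str)
        for gene, prot in zip(gp.iloc[:, 0].str.strip(), gp.iloc[:, 1].str.strip()):
            if not prot:
                raise ValueError(f"empty protein id mapped from gene {gene!r}")
            g2p.setdefault(gene, set()).add(prot)
        t2g: dict[str, str] = {}
        if transcript_gene_path is not None:
            tg = pd.read_csv(transcript_gene_path, sep="\t", dtype=str)
            t2g = dict(zip(tg.iloc[:, 0].str.strip(), tg.iloc[:, 1].str.strip()))
        return cls(
            gene_to_proteins={g: frozenset(p) for g, p in g2p.items()},
            transcript_to_gene=t2g,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_selection_rule(study: MarkerStudy) -> frozenset[str]:
    """Extract the gene set passing the study's selection rule.

    Duplicate gene ids are deduplicated (logged) before the rule is applied.
    FC rules operate on the raw fold-change scale and log2fc rules on the log
    scale; no silent conversion between the two.
    """
    rule = study.rule
    table = study.table
    if "gene_id" not in table.columns:
        raise ValueError(f"{study.study_id}: table lacks a gene_id column")
    n_dup = int(table["gene_id"].duplicated().sum())
    if n_dup:
        logger.info("%s: %d duplicate gene rows deduplicated", study.study_id, n_dup)
        table = table.drop_duplicates(subset="gene_id", keep="first")

    if rule.statistic == "all":
        return frozenset(table["gene_id"].str.strip())

    if rule.statistic not in table.columns:
        raise ValueError(
            f"{study.study_id}: rule statistic {rule.statistic!r} not a table column"
        )
    vals = table[rule.statistic].astype(float)
    mask = vals > rule.threshold if rule.strict else vals >= rule.threshold
    if rule.adj_p_max is not None:
        if "adj_pvalue" not in table.columns:
            raise ValueError(f"{study.study_id}: rule needs adj_pvalue column")
        mask &= table["adj_pvalue"].astype(float) <= rule.adj_p_max
    return frozenset(table.loc[mask, "gene_id"].str.strip())


def combine(sets, mode: str) -> frozenset[str]:
    """Set union or intersection of one or more gene sets."""
    sets = [frozenset(s) for s in sets]
    if not sets:
        raise ValueError("combine requires at least one set")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown combination mode {mode!r}")
    out = sets[0]
    for s in sets[1:]:
        out = out | s if mode == "union" else out & s
    return out


def finalize_against(
    raw, universe: DEDataset, name: str, combination: str = "single"
) -> MarkerList:
    """Detection-filter a raw gene set against the focal universe.

    ``detected_members`` is the intersection of the raw members with the gene
    ids present in the universe (transcript universes are gene-keyed; protein
    universes key on the protein id itself).  Re-finalizing a finalized list
    against the same universe is a no-op.
    """
    if universe.n_detected == 0:
        raise ValueError("cannot finalize against an empty universe")
    raw = frozenset(raw)
    detected = raw & universe.detected_keys()
    return MarkerList(
        name=name,
        combination=combination,
        raw_members=raw,
        detected_members=detected,
        modality=universe.modality,
    )


def map_to_protein_universe(
    lst: MarkerList, idmap: IdMap, protein_universe: DEDataset
) -> MarkerList:
    """Convert a gene-level marker list into a protein-level one.

    Matching is at the encoding-gene level: *any* detected protein product of
    a list gene counts, never a specific isoform.  A gene with k detected
    isoforms contributes up to k members.  Unmapped genes contribute nothing
    (logged count).
    """
    if protein_universe.modality != "protein":
        raise ValueError("protein_universe must have modality 'protein'")
    detected_proteins = protein_universe.detected_keys()
    members: set[str] = set()
    n_unmapped = 0
    for gene in lst.raw_members:
        isoforms = idmap.proteins_of(gene)
        if not isoforms:
            n_unmapped += 1
            continue
        members |= isoforms & detected_proteins
    if n_unmapped:
        logger.info("%s: %d genes with no protein mapping", lst.name, n_unmapped)
    members_f = frozenset(members)
    return MarkerList(
        name=lst.name,
        combination=lst.combination,
        raw_members=members_f,
        detected_members=members_f,
        modality="protein",
    )


# ---------------------------------------------------------------------------
# declarative compilation config
# ---------------------------------------------------------------------------

def load_study(path, study_id: str, rule: SelectionRule, sep: str = "\t") -> MarkerStudy:
    table = pd.read_csv(path, sep=sep, dtype={"gene_id": str})
    return MarkerStudy(study_id=study_id, table=table, rule=rule)


def _rule_from_dict(d: dict) -> SelectionRule:
    return SelectionRule(
        statistic=d.get("statistic", "all"),
        threshold=d.get("threshold"),
        adj_p_max=d.get("adj_p_max"),
        description=d.get("description", ""),
    )


def compile_from_config(config, base_dir=None) -> dict[str, tuple[str, frozenset[str]]]:
    """Compile raw marker lists from a declarative YAML config.

    The config carries one entry per list: name, combination mode, and one
    {id, file, rule} block per source study.  Returns
    ``{name: (combination, raw_member_set)}``; callers finalize against their
    universe with :func:`finalize_against`.
    """
    if not isinstance(config, dict):
        base_dir = Path(config).parent if base_dir is None else Path(base_dir)
        with open(config) as fh:
            config = yaml.safe_load(fh)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    out: dict[str, tuple[str, frozenset[str]]] = {}
    for entry in config["lists"]:
        name = entry["name"]
        combination = entry.get("combination", "single")
        member_sets = []
        for block in entry["studies"]:
            study = load_study(
                base_dir / block["file"],
                study_id=block.get("id", block["file"]),
                rule=_rule_from_dict(block.get("rule", {})),
            )
            member_sets.append(apply_selection_rule(study))
        mode = "union" if combination in ("single", "union") else "intersection"
        out[name] = (combination, combine(member_sets, mode))
    return out
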