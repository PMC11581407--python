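"""Immune-gene classification by four disjunctive criteria.

A gene is flagged "immune" when it satisfies any of: (1) presence in a curated
immune-factor list, (2) carrying at least one immune-function GO annotation
(supplied as a precomputed gene set), (3) induction in any immune-challenge
marker list, or (4) status as an activated-macrophage or lamellocyte marker.
Subclassification into humoral / cellular / both is a manual-curation overlay,
not an algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

CRITERIA = ("curated", "go", "challenge", "cell_marker")
SUBCLASSES = ("humoral", "cellular", "humoral_cellular", "unclear", "none")


@dataclass
class ClassificationResource:
    curated_immune_genes: frozenset[str] = frozenset()
    go_immune_annotated: frozenset[str] = frozenset()
    immune_challenge_members: frozenset[str] = frozenset()
    activated_cell_markers: frozenset[str] = frozenset()

    @classmethod
    def from_files(cls, curated=None, go=None, challenge=None, cell_marker=None):
        """Build from plain one-gene-per-line text files (None -> empty set)."""
        def read(path):
            if path is None:
                return frozenset()
            lines = Path(path).read_text().splitlines()
            return frozenset(g.strip() for g in lines if g.strip())

        return cls(read(curated), read(go), read(challenge), read(cell_marker))

    def _sets(self):
        return {
            "curated": self.curated_immune_genes,
            "go": self.go_immune_annotated,
            "challenge": self.immune_challenge_members,
            "cell_marker": self.activated_cell_markers,
        }


@dataclass(frozen=True)
class ImmuneCall:
    gene_id: str
    is_immune: bool
    criteria_met: frozenset[str] = frozenset()
    subclass: str = "none"

    def __post_init__(self):
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if self.is_immune != bool(self.criteria_met):
            raise ValueError("is_immune must reflect a nonempty criteria set")


def classify_immune(
    genes,
    res: ClassificationResource,
    curation: dict[str, str] | None = None,
) -> list[ImmuneCall]:
    """Classify genes by the four-criterion disjunction.

    Deterministic and order-independent (output sorted by gene id).  The
    optional ``curation`` mapping assigns a humoral/cellular subclass to
    immune genes; without it every immune gene is subclassed "unclear".
    """
    curation = curation or {}
    sets = res._sets()
    calls = []
    for gene in sorted(set(genes)):
        met = frozenset(name for name, members in sets.items() if gene in members)
        if met:
            subclass = curation.get(gene, "unclear")
            if subclass == "none":
                raise ValueError(f"curation maps immune gene {gene!r} to 'none'")
        else:
            subclass = "none"
        calls.append(
            ImmuneCall(gene_id=gene, is_immune=bool(met), criteria_met=met, subclass=subclass)
        )
    return calls


def load_curation(path) -> dict[str, str]:
    """Read a two-column TSV (gene, subclass) curation overlay."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, subclass = line.split("\t")[:2]
        if subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {subclass!r} for gene {gene!r}")
        out[gene.strip()] = subclass.strip()
    return out


def calls_to_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tis_immune\tcriteria_met\tsubclass\n")
        for c in calls:
            crit = ",".join(sorted(c.criteria_met))
            fh.write(f"{c.gene_id}\t{str(c.is_immune).lower()}\t{crit}\t{c.subclass}\n")
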