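"""Model/Results interface for the marker-list overlap battery.

Follows the familiar two-object pattern: a :class:`MarkerOverlapModel` is built
from data (the compiled marker lists plus one or two detected universes) and
``fit()`` returns a :class:`MarkerOverlapResults` carrying per-list estimates
(overlap fraction, fold enrichment), their Fisher exact p-values and odds
ratios, and a ``summary()`` table mirroring the layout of published
marker-comparison tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .de_table import DEDataset, format_percent
from .marker_lists import IdMap, MarkerList, map_to_protein_universe

_FRAME_COLUMNS = [
    "list", "modality", "n_raw", "n_detected", "n_overlap",
    "overlap_pct", "background_pct", "fold_enrichment", "fisher_p", "odds_ratio",
]


class MarkerOverlapModel:
    """Overlap-enrichment model for a battery of marker lists.

    Parameters
    ----------
    lists : iterable of MarkerList
        Finalized (detection-filtered) gene-level marker lists.
    universe : DEDataset
        The focal transcript universe with direction calls.
    protein_universe, idmap : optional
        When both are given, each list is additionally mapped to protein
        isoforms (any protein product of a list gene matches) and scored
        against the protein universe.
    background, protein_background : float, optional
        Override the chance-level fraction; defaults to each universe's own
        increased fraction.
    sidedness : {"greater", "two_sided"}
        Fisher test sidedness; the directional one-sided test is the default.
    """

    def __init__(
        self,
        lists,
        universe: DEDataset,
        *,
        protein_universe: DEDataset | None = None,
        idmap: IdMap | None = None,
        direction: str = "increased",
        background: float | None = None,
        protein_background: float | None = None,
        sidedness: str = "greater",
    ):
        self.lists = list(lists)
        self.universe = universe
        self.protein_universe = protein_universe
        self.idmap = idmap
        self.direction = direction
        self.background = background
        self.protein_background = protein_background
        self.sidedness = sidedness
        if protein_universe is not None and idmap is None:
            raise ValueError("a protein universe requires an id map")

    def fit(self) -> "MarkerOverlapResults":
        from .enrichment import overlap_enrichment

        results = []
        for lst in self.lists:
            results.append(
                overlap_enrichment(
                    lst, self.universe,
                    direction=self.direction,
                    background=self.background,
                    sidedness=self.sidedness,
                )
            )
            if self.protein_universe is not None:
                plist = map_to_protein_universe(lst, self.idmap, self.protein_universe)
                results.append(
                    overlap_enrichment(
                        plist, self.protein_universe,
                        direction=self.direction,
                        background=self.protein_background,
                        sidedness=self.sidedness,
                    )
                )
        return MarkerOverlapResults(self, results)


class MarkerOverlapResults:
    """Fitted battery results; indexable by (list name, modality)."""

    def __init__(self, model: MarkerOverlapModel, results):
        self.model = model
        self.results = list(results)
        self._by_key = {(r.list_name, r.modality): r for r in self.results}

    def __getitem__(self, key):
        if isinstance(key, str):
            key = (key, self.model.universe.modality)
        return self._by_key[key]

    def __iter__(self):
        return iter(self.results)

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "list": r.list_name,
                "modality": r.modality,
                "n_raw": r.n_raw,
                "n_detected": r.n_list_detected,
                "n_overlap": r.n_overlap,
                "overlap_pct": 100.0 * r.overlap_fraction,
                "background_pct": 100.0 * r.background_fraction,
                "fold_enrichment": r.fold_enrichment,
                "fisher_p": r.fisher_p,
                "odds_ratio": r.odds_ratio,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=_FRAME_COLUMNS)

    def summary(self) -> str:
        """Human-readable battery table (one row per list x modality)."""
        df = self.frame.copy()
        df["overlap_pct"] = df["overlap_pct"].map(lambda x: f"{x:.1f}")
        df["background_pct"] = df["background_pct"].map(lambda x: f"{x:.2f}")
        df["fold_enrichment"] = df["fold_enrichment"].map(lambda x: f"{x:.2f}")
        df["fisher_p"] = df["fisher_p"].map(lambda x: f"{x:.3g}")
        df["odds_ratio"] = df["odds_ratio"].map(lambda x: f"{x:.3g}")
        title = "Marker-list overlap enrichment"
        sub = (
            f"universe: {self.model.universe.n_detected} detected, "
            f"{self.model.universe.n_direction(self.model.direction)} {self.model.direction} "
            f"({format_percent(self.model.universe.n_direction(self.model.direction) / self.model.universe.n_detected, 2)}); "
            f"Fisher sidedness: {self.model.sidedness}"
        )
        body = df.to_string(index=False)
        rule = "=" * max(len(line) for line in body.splitlines())
        return "\n".join([title, sub, rule, body, rule])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = [asdict(r) for r in self.results]
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
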