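"""End-to-end identification pipeline and reporting.

Orchestrates the full analysis: classify every query with the hierarchical
character key and with neighbour-joining tree placement, apply the 1%
divergence gate (a BOLD-style no-match threshold on the minimum
query-to-reference p-distance), run the two-marker introgression concordance
check, and emit composition tables and a method-comparison report.

Final-call precedence: the character-key call stands, overridden only by the
second-marker introgression rule; the tree call is reported alongside, never
silently merged.  Gate failures are annotated, not dropped — the character
key still classifies them — but the distance-based (tree) method reports
gate-failed queries as unidentified, since a query with no reference within
the divergence threshold has no cluster to join.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ca_key import (
    AssignmentResult,
    IdentificationKey,
    LEVEL_RESIDUAL,
    STRICT,
    UNIDENTIFIED,
    build_hierarchical_key,
    classify_query,
)
from .distances import P_DISTANCE, distances_to_references
from .njtree import (
    DEFAULT_SATURATION_CAP,
    PhyloTree,
    TreeAssignment,
    assign_by_tree,
    bootstrap_supports,
    build_distance_matrix,
    nj_build,
    to_newick,
)
from .seqio import Alignment, TaxonomyTable
from .synthetic_data import NON_SCOMBRID

DEFAULT_GATE_THRESHOLD = 0.01


@dataclass(frozen=True)
class GateResult:
    """Divergence-gate outcome for one query."""

    query_id: str
    passed: bool
    min_distance: float | None
    nearest_reference: str | None
    reason: str | None = None


def divergence_gate(
    query: str,
    references: Alignment,
    threshold: float = DEFAULT_GATE_THRESHOLD,
    query_id: str = "query",
) -> GateResult:
    """Fail iff the minimum p-distance to any reference exceeds *threshold*.

    Failed queries are reported as "no match" by the distance method but are
    still passed to the character key downstream.
    """
    d = distances_to_references(query, references)
    if np.isnan(d).all():
        return GateResult(query_id, False, None, None,
                          reason="no comparable sites against any reference")
    k = int(np.nanargmin(d))
    dmin = float(d[k])
    return GateResult(query_id, dmin <= threshold, dmin, references.ids[k])


@dataclass
class CompositionTable:
    """Counts of final species calls by sampling site, with totals.

    Rows are taxa (non-scombrid / unidentified queries pooled under
    ``"Non-scombrid larvae"``), columns are sites.  Marginal totals always
    equal the per-site query counts.
    """

    counts: pd.DataFrame  # species x site, integer counts

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("composition counts must be non-negative")
        self.counts = self.counts.astype(int)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def site_totals(self) -> dict[str, int]:
        return {s: int(v) for s, v in self.counts.sum(axis=0).items()}

    def species_total(self, name: str) -> int:
        if name not in self.counts.index:
            return 0
        return int(self.counts.loc[name].sum())

    def genus_total(self, genus: str) -> int:
        mask = self.counts.index.str.startswith(genus + " ")
        return int(self.counts.loc[mask].to_numpy().sum())

    def count(self, name: str, site: str) -> int:
        if name not in self.counts.index or site not in self.counts.columns:
            return 0
        return int(self.counts.loc[name, site])

    def share_pct(self, name: str) -> float:
        """Share of the grand total, in percent (rounded to whole percent)."""
        return round(100.0 * self.species_total(name) / self.grand_total)

    def with_totals(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.with_totals().to_csv(path, sep="\t", index_label="Species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompositionTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame = frame.drop(index="Total", errors="ignore")
        frame = frame.drop(columns="Total", errors="ignore")
        return cls(frame)


def composition_table(
    final_calls: Mapping[str, str | None],
    site_map: Mapping[str, str],
    sites: Sequence[str] | None = None,
) -> CompositionTable:
    """Tabulate final calls by site; unidentified queries pool as non-scombrid."""
    missing = [q for q in final_calls if q not in site_map]
    if missing:
        raise ValueError(f"queries with no site: {missing[:5]}")
    if sites is None:
        sites = list(dict.fromkeys(site_map[q] for q in final_calls))
    rows: dict[str, dict[str, int]] = {}
    for q, call in final_calls.items():
        label = call if call and call != UNIDENTIFIED else NON_SCOMBRID
        rows.setdefault(label, {})
        site = site_map[q]
        rows[label][site] = rows[label].get(site, 0) + 1
    species = sorted(lab for lab in rows if lab != NON_SCOMBRID)
    if NON_SCOMBRID in rows:
        species.append(NON_SCOMBRID)
    frame = pd.DataFrame(
        [[rows.get(sp, {}).get(site, 0) for site in sites] for sp in species],
        index=species, columns=list(sites),
    )
    return CompositionTable(frame)


@dataclass(frozen=True)
class ConcordanceRow:
    query_id: str
    marker1_call: str
    marker2_call: str
    status: str  # confirmed | introgressed | unconfirmed | missing
    final_call: str


@dataclass
class ConcordanceReport:
    """Second-marker check over the introgression-suspect queries."""

    rows: list[ConcordanceRow]

    @property
    def introgressed_ids(self) -> frozenset[str]:
        return frozenset(r.query_id for r in self.rows if r.status == "introgressed")

    @property
    def overrides(self) -> dict[str, str]:
        return {
            r.query_id: r.final_call
            for r in self.rows
            if r.status == "introgressed"
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def confirm_with_second_marker(
    suspects: Mapping[str, str],
    key2: IdentificationKey,
    marker2_queries: Alignment,
    recipient: str = "Thunnus thynnus",
) -> ConcordanceReport:
    """Check introgression suspects against the nuclear second marker.

    *suspects* maps query id -> barcode-marker call (the donor species or a
    residual group).  Each suspect is classified on the second marker:
    a concordant call confirms the identification; a discordant call equal to
    *recipient* flags mitochondrial introgression and the final call is
    overridden to the recipient with provenance retained in the report.
    Suspects missing from the second-marker set are listed as such.
    """
    ids2 = set(marker2_queries.ids)
    rows: list[ConcordanceRow] = []
    for qid in sorted(suspects):
        m1 = suspects[qid]
        if qid not in ids2:
            rows.append(ConcordanceRow(qid, m1, "", "missing", m1))
            continue
        res = classify_query(key2, marker2_queries[qid].seq, query_id=qid)
        m2 = res.taxon
        if m2 == recipient and m1 != recipient:
            rows.append(ConcordanceRow(qid, m1, m2, "introgressed", recipient))
        elif m2 == m1 or (res.level == LEVEL_RESIDUAL and m1 in res.candidate_species):
            rows.append(ConcordanceRow(qid, m1, m2, "confirmed", m1))
        else:
            rows.append(ConcordanceRow(qid, m1, m2, "unconfirmed", m1))
    return ConcordanceReport(rows)


@dataclass
class MethodComparison:
    """Agreement between per-query assignments of two or more methods."""

    assignments: pd.DataFrame  # query x method
    agreement_rate: float
    discordant: pd.DataFrame
    gate_failed: tuple[str, ...] = ()
    introgression_suspects: tuple[str, ...] = ()


def compare_methods(
    results: Mapping[str, Mapping[str, str | None]],
    gate_failed: Iterable[str] = (),
    introgression_suspects: Iterable[str] = (),
) -> MethodComparison:
    """Compare per-query calls across methods.

    Agreement is computed over queries *assigned by every method* (unidentified
    or missing calls are excluded from the denominator).
    """
    if len(results) < 2:
        raise ValueError("need at least two methods to compare")
    methods = list(results)
    common: set[str] | None = None
    for calls in results.values():
        common = set(calls) if common is None else common & set(calls)
    if not common:
        raise ValueError("methods have disjoint query sets")
    table = pd.DataFrame(
        {m: {q: results[m].get(q) for q in sorted(common)} for m in methods}
    )
    assigned = table.dropna()
    assigned = assigned[(assigned != UNIDENTIFIED).all(axis=1)]
    if len(assigned):
        agree = (assigned.nunique(axis=1) == 1)
        rate = float(agree.mean())
        discordant = assigned[~agree]
    else:
        rate = float("nan")
        discordant = assigned
    return MethodComparison(
        table, rate, discordant,
        tuple(sorted(gate_failed)), tuple(sorted(introgression_suspects)),
    )


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    assignments: pd.DataFrame
    ca_results: dict[str, AssignmentResult]
    tree: PhyloTree
    tree_assignments: dict[str, TreeAssignment]
    gates: dict[str, GateResult]
    concordance: ConcordanceReport
    composition: CompositionTable
    nj_composition: CompositionTable
    comparison: MethodComparison
    key: IdentificationKey
    manifest: dict

    def final_calls(self) -> dict[str, str | None]:
        return dict(zip(self.assignments.index, self.assignments["final_call"]))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assignments": outdir / "assignments.tsv",
            "composition": outdir / "composition.tsv",
            "nj_composition": outdir / "nj_composition.tsv",
            "comparison": outdir / "comparison.tsv",
            "concordance": outdir / "concordance.tsv",
            "tree": outdir / "tree.nwk",
            "manifest": outdir / "manifest.json",
        }
        self.assignments.to_csv(paths["assignments"], sep="\t", index_label="query")
        self.composition.to_tsv(paths["composition"])
        self.nj_composition.to_tsv(paths["nj_composition"])
        self.comparison.assignments.to_csv(
            paths["comparison"], sep="\t", index_label="query"
        )
        self.concordance.to_frame().to_csv(paths["concordance"], sep="\t", index=False)
        paths["tree"].write_text(to_newick(self.tree) + "\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _ca_call(res: AssignmentResult) -> str | None:
    return None if res.taxon == UNIDENTIFIED else res.taxon


def run_pipeline(
    references: Alignment,
    taxonomy: TaxonomyTable,
    queries: Alignment,
    site_map: Mapping[str, str] | None = None,
    key: IdentificationKey | None = None,
    model: str = P_DISTANCE,
    bootstrap: int = 0,
    gate_threshold: float = DEFAULT_GATE_THRESHOLD,
    marker2_queries: Alignment | None = None,
    key2: IdentificationKey | None = None,
    recipient: str = "Thunnus thynnus",
    donor: str = "Thunnus alalunga",
    seed: int = 0,
    max_compound: int = 3,
    mode: str = STRICT,
) -> PipelineResult:
    """Run the full identification analysis.

    If *key* is None it is discovered from the reference panel.  Suspects for
    the introgression check are the queries whose character-key call is the
    donor species or a residual group; the check runs only when both *key2*
    and *marker2_queries* are provided.
    """
    if key is None:
        key = build_hierarchical_key(references, taxonomy, max_compound=max_compound)
    if references.length != queries.length:
        raise ValueError("queries are not on the reference frame")
    if site_map is None:
        site_map = {q: "all" for q in queries.ids}

    ca_results = {
        q.id: classify_query(key, q.seq, mode=mode, query_id=q.id) for q in queries
    }
    ca_calls = {qid: _ca_call(r) for qid, r in ca_results.items()}

    gates = {
        q.id: divergence_gate(q.seq, references, gate_threshold, query_id=q.id)
        for q in queries
    }
    gate_failed = {qid for qid, g in gates.items() if not g.passed}

    combined = Alignment(list(references.records) + list(queries.records))
    if bootstrap > 0:
        tree = bootstrap_supports(combined, model=model, n_reps=bootstrap, seed=seed)
    else:
        dm = build_distance_matrix(combined, model,
                                   saturation_cap=DEFAULT_SATURATION_CAP)
        tree = nj_build(dm)
    tree_assignments = assign_by_tree(tree, taxonomy.species_map(), queries.ids)
    nj_calls: dict[str, str | None] = {
        qid: (None if qid in gate_failed else a.species)
        for qid, a in tree_assignments.items()
    }

    # introgression concordance on the second marker
    residual_names = {c.name for c in key.clades if c.level == LEVEL_RESIDUAL}
    suspects = {
        qid: call
        for qid, call in ca_calls.items()
        if call is not None and (call == donor or call in residual_names)
    }
    if key2 is not None and marker2_queries is not None:
        concordance = confirm_with_second_marker(
            suspects, key2, marker2_queries, recipient=recipient
        )
    else:
        concordance = ConcordanceReport([])
    final_calls = dict(ca_calls)
    final_calls.update(concordance.overrides)

    composition = composition_table(final_calls, site_map)
    nj_composition = composition_table(nj_calls, site_map)
    comparison = compare_methods(
        {"ca_key": ca_calls, "nj_tree": nj_calls},
        gate_failed=gate_failed,
        introgression_suspects=suspects,
    )

    assignments = pd.DataFrame(
        {
            "site": [site_map[q] for q in queries.ids],
            "ca_call": [ca_calls[q] for q in queries.ids],
            "ca_level": [ca_results[q].level for q in queries.ids],
            "ca_flags": [";".join(sorted(ca_results[q].flags)) for q in queries.ids],
            "nj_call": [nj_calls[q] for q in queries.ids],
            "nj_raw": [tree_assignments[q].species for q in queries.ids],
            "gate_passed": [gates[q].passed for q in queries.ids],
            "min_distance": [gates[q].min_distance for q in queries.ids],
            "introgressed": [q in concordance.introgressed_ids for q in queries.ids],
            "final_call": [final_calls[q] for q in queries.ids],
        },
        index=pd.Index(queries.ids, name="query"),
    )
    manifest = {
        "package_version": __version__,
        "model": model,
        "bootstrap_replicates": bootstrap,
        "gate_threshold": gate_threshold,
        "seed": seed,
        "mode": mode,
        "n_references": len(references),
        "n_queries": len(queries),
        "frame_length": references.length,
        "key_provenance": dict(key.provenance),
        "second_marker_checked": bool(key2 is not None and marker2_queries is not None),
    }
    return PipelineResult(
        assignments=assignments,
        ca_results=ca_results,
        tree=tree,
        tree_assignments=tree_assignments,
        gates=gates,
        concordance=concordance,
        composition=composition,
        nj_composition=nj_composition,
        comparison=comparison,
        key=key,
        manifest=manifest,
    )
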