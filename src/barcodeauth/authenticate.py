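"""Query identification against the reference barcode library.

Identification is exhaustive nearest-neighbor under global pairwise alignment
with free end gaps (BLAST-style "maximum identity" semantics: the reported
percent identity of the best single reference per species).  An 8-mer shared-
count prefilter skips references that cannot be close, with an exactness-
preserving fallback to the full scan.  Species calls combine the identity
threshold with the target's diagnostic-site verdicts, and the PCR-RFLP assay
outcome is predicted for every query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .assay import AssayDesign, PcrConstraints, digest, in_silico_pcr
from .diagnostics import DiagnosticSite, SiteCheck, check_query_diagnostics
from .seqio import Alignment, SampleTable, SequenceRecord
from .stats import map_query_to_alignment

__all__ = [
    "IdentificationResult",
    "identity_percent",
    "identify",
    "predict_assay",
    "batch_report",
    "composition_summary",
]


def _make_identity_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    # free end gaps on both sequences
    a.open_end_insertion_score = 0
    a.extend_end_insertion_score = 0
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    return a


_IDENTITY_ALIGNER = _make_identity_aligner()


def _round1_half_up(x: float) -> float:
    return math.floor(x * 10.0 + 0.5) / 10.0


def identity_percent(a: str, b: str) -> float:
    """Percent identity (1 d.p., half-up) of two ungapped sequences under a
    global alignment with free end gaps; terminal overhangs are excluded from
    the aligned-column count."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _IDENTITY_ALIGNER.align(a.upper(), b.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    # core = columns between the first and last positions where both rows
    # have a residue (terminal free-gap overhangs excluded)
    both = [k for k in range(len(ra)) if ra[k] != "-" and rb[k] != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    cols = hi - lo + 1
    matches = sum(1 for k in range(lo, hi + 1) if ra[k] == rb[k] and ra[k] != "-")
    return _round1_half_up(100.0 * matches / cols)


@dataclass
class IdentificationResult:
    """Ranked species hits for one query, plus assay and diagnostic verdicts."""

    query_id: str
    hits: list[tuple[str, float]]  # (species, percent identity of best member), descending
    top_species: list[str] = field(default_factory=list)  # ties preserved
    best_ref_id: str = ""  # library member realizing the overall best identity
    diagnostics: list[SiteCheck] = field(default_factory=list)
    diagnostics_pass: bool | None = None
    specific_pcr: str = ""  # '+' | '-'
    rflp: str = ""  # '+' | '-' | 'N/A'
    final_call: str = ""

    @property
    def top_identity(self) -> float:
        return self.hits[0][1] if self.hits else 0.0


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def identify(query: SequenceRecord, library: Sequence[SequenceRecord],
             table: SampleTable, *, k: int = 8, prefilter: bool = True,
             species_threshold: float = 99.0) -> IdentificationResult:
    """Best-match identification of one query against the library.

    Per-species maximum identity is computed against the best single reference
    of that species; species tied at the top identity are all listed.  The
    k-mer prefilter only skips references sharing no k-mer with the query and
    falls back to the full scan if it would skip everything.
    """
    if not library:
        raise ValueError("library must be non-empty")
    q = query.residues.replace("-", "")
    refs = list(library)
    if prefilter:
        qk = _kmers(q, k)
        kept = [r for r in refs if qk & _kmers(r.ungapped, k)]
        if kept:
            refs = kept
    # identical reference sequences share one alignment
    by_seq: dict[str, list[SequenceRecord]] = {}
    for ref in refs:
        by_seq.setdefault(ref.ungapped, []).append(ref)
    best_by_species: dict[str, float] = {}
    best_ref_id, best_overall = "", -1.0
    for seq, members in by_seq.items():
        ident = identity_percent(q, seq)
        if ident > best_overall:
            best_overall, best_ref_id = ident, members[0].id
        for ref in members:
            sp = table.species_of(ref.id)
            if ident > best_by_species.get(sp, -1.0):
                best_by_species[sp] = ident
    hits = sorted(best_by_species.items(), key=lambda kv: (-kv[1], kv[0]))
    top = hits[0][1]
    top_species = [sp for sp, ident in hits if ident == top]
    res = IdentificationResult(query_id=query.id, hits=hits, top_species=top_species,
                               best_ref_id=best_ref_id)
    res.final_call = _final_call(res, species_threshold)
    return res


def _final_call(res: IdentificationResult, species_threshold: float) -> str:
    if not res.hits or res.top_identity < species_threshold:
        return "unresolved"
    if len(res.top_species) > 1:
        return "/".join(res.top_species)
    call = res.top_species[0]
    if res.diagnostics_pass is False:
        return f"{call} (genus-level)"
    return call


def predict_assay(query: SequenceRecord, design: AssayDesign,
                  constraints: PcrConstraints = PcrConstraints()) -> tuple[str, str]:
    """Specific-PCR / PCR-RFLP readout for one query: no amplicon -> (-, N/A);
    amplicon uncut -> (+, -); amplicon cut -> (+, +)."""
    amps = in_silico_pcr(query.ungapped, design.fwd, design.rev, constraints, query.id)
    if not amps:
        return "-", "N/A"
    pattern = digest(amps[0], design.enzyme)
    return "+", "+" if len(pattern.fragments) > 1 else "-"


def batch_report(queries: Sequence[SequenceRecord], library: Sequence[SequenceRecord],
                 table: SampleTable, designs: Sequence[AssayDesign] = (),
                 diagnostics: Sequence[DiagnosticSite] = (),
                 library_alignment: Alignment | None = None,
                 *, products: Mapping[str, str] | None = None,
                 target: str = "", species_threshold: float = 99.0,
                 constraints: PcrConstraints = PcrConstraints()) -> pd.DataFrame:
    """Authentication report: one row per query sequence.

    ``products`` maps query ids to product ids (several sequences cloned from
    one commercial product); products whose sequences identify to more than one
    species are flagged as mixtures.  Columns mirror a market-survey table:
    identified organism, maximum identity, specific-PCR and PCR-RFLP outcomes,
    and the final call.
    """
    products = dict(products) if products else {q.id: q.id for q in queries}
    design = designs[0] if designs else None
    rows = []
    results: list[IdentificationResult] = []
    for q in queries:
        res = identify(q, library, table, species_threshold=species_threshold)
        if diagnostics and library_alignment is not None:
            ref_hint = res.best_ref_id if res.best_ref_id in set(library_alignment.ids()) else None
            aligned = map_query_to_alignment(library_alignment, q.ungapped, ref_hint)
            res.diagnostics, res.diagnostics_pass = check_query_diagnostics(aligned, diagnostics)
            res.final_call = _final_call(res, species_threshold)
        if design is not None:
            res.specific_pcr, res.rflp = predict_assay(q, design, constraints)
        results.append(res)
    # mixture detection per product id
    by_product: dict[str, set[str]] = {}
    for q, res in zip(queries, results):
        pid = products.get(q.id, q.id)
        by_product.setdefault(pid, set()).add("/".join(res.top_species))
    for q, res in zip(queries, results):
        pid = products.get(q.id, q.id)
        rows.append({
            "product_id": pid,
            "sequence_id": q.id,
            "length": len(q.ungapped),
            "identified_organism": "/".join(res.top_species),
            "maximum_identity": res.top_identity,
            "diagnostics_pass": res.diagnostics_pass,
            "specific_pcr": res.specific_pcr,
            "pcr_rflp": res.rflp,
            "final_call": res.final_call,
            "mixture": len(by_product[pid]) > 1,
        })
    df = pd.DataFrame(rows, columns=["product_id", "sequence_id", "length",
                                     "identified_organism", "maximum_identity",
                                     "diagnostics_pass", "specific_pcr", "pcr_rflp",
                                     "final_call", "mixture"])
    return df


def composition_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Species-composition counts over products (one vote per product/organism)."""
    if report.empty:
        return pd.DataFrame(columns=["species", "count", "percent"])
    per_product = report.drop_duplicates(["product_id", "identified_organism"])
    counts = per_product.groupby("identified_organism").size().sort_values(ascending=False)
    n_products = report["product_id"].nunique()
    out = pd.DataFrame({
        "species": counts.index,
        "count": counts.values,
        "percent": (100.0 * counts.values / n_products).round(1),
    })
    return out.reset_index(drop=True)
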