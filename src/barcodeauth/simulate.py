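"""Synthetic reference libraries and market-product queries.

The generator emulates the structure the analysis assumes: one target species
with low intraspecific divergence, a set of congeners at small interspecific
divergences, distant adulterants, and the planted features the assay-design
stage must rediscover — two diagnostic characters in the target (a 1-nt
deletion and a substitution), conserved primer landing sites flanking the
barcode, a restriction site completed only by the target's diagnostic
substitution, and a confounding restriction site shared by target and
congeners underneath the reverse-primer footprint.

Sequences are built in a fixed 301-column coordinate frame (45-nt flank,
211-nt barcode, 45-nt flank); the target's planted deletion appears as ``-``
in that frame, so the true alignment is known by construction.  Substitutions
follow a per-site Kimura 2-parameter process (transitions favored by kappa);
planted features are written first and protected from mutation so the truth
ledger stays exact.  Between-species divergence is applied as a deterministic
substitution count (``round(divergence x free sites)``) so the configured
study conditions are realized at every seed; within-species and query
variation is Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assay import BGL_I, ITS2F, Enzyme, Primer, find_motif_sites
from .seqio import Alignment, SampleTable, SequenceRecord, reverse_complement
import pandas as pd

__all__ = ["SyntheticConfig", "TruthLedger", "simulate_library", "simulate_products",
           "default_composition"]

# Fixed layout of the 301-column ancestral frame (1-based, inclusive).
_FLANK = 45
_BARCODE = (46, 256)  # 211 columns
_FWD_FOOTPRINT = (6, 25)  # ITS2F, 20 nt
_REV_FOOTPRINT = (280, 298)  # reverse primer, 19 nt
_DIAG_INDEL = 113  # barcode column 68: G in everything but the target
_DIAG_MOTIF = (168, 178)  # Bgl I site completed only by the target
_DIAG_SUB = 178  # barcode column 133: A ancestrally, C in the target
_CONF_MOTIF = (284, 294)  # confounding Bgl I site shared with congeners
_ENGINEERED_PRIMER_POS = 13  # 5'-counted primer base replaced G -> T

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic library.

    Defaults mirror the reference study's printed statistics: a 211-bp barcode
    at 64.5% GC, target intraspecific mean K2P near 0.006, congeneric
    divergences spanning roughly 0.01-0.05, and clearly separated adulterants.
    """

    seed: int = 1
    n_congener_species: int = 11
    n_adulterant_species: int = 10
    samples_per_species: int = 5
    barcode_length: int = 211
    flank_length: int = 45
    kappa: float = 4.0
    intra_subs: float = 0.6
    congener_divergence: float = 0.02
    genus_stem_divergence: float = 0.08
    adulterant_divergence: float = 0.25
    gc_target: float = 0.645

    def __post_init__(self) -> None:
        if self.barcode_length != 211 or self.flank_length != _FLANK:
            raise ValueError("the planted-feature layout requires barcode_length=211, "
                             "flank_length=45")
        if not (0 < self.congener_divergence < 1 and 0 < self.adulterant_divergence < 1
                and 0 < self.genus_stem_divergence < 1):
            raise ValueError("divergences must lie in (0, 1)")
        if self.n_congener_species < 1 or self.n_adulterant_species < 1:
            raise ValueError("need at least one congener and one adulterant species")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species must be >= 1")
        last = _CONF_MOTIF[1]
        if last > 2 * self.flank_length + self.barcode_length:
            raise ValueError("planted features fall outside the template")


@dataclass
class TruthLedger:
    """Everything the generator planted, for closed-loop verification."""

    config: SyntheticConfig
    template_length: int
    barcode_span: tuple[int, int]
    samples: dict[str, str]  # sample_id -> species
    species_groups: dict[str, str]
    species_divergence: dict[str, float]
    aligned_rows: dict[str, str]  # 301-column frame, '-' at the target deletion
    diagnostic_sites_barcode: list[dict]  # frame: barcode alignment columns
    fwd_primer: str
    rev_primer_base: str
    rev_primer_engineered: str
    rev_footprint: tuple[int, int]
    rev_footprint_template: tuple[int, int]  # same interval in target-template coords
    engineered_position: int
    enzyme: str
    target_species: str
    expected_amplicon_length: int
    expected_fragments: tuple[int, int]

    def barcode_alignment(self, table: SampleTable) -> Alignment:
        lo, hi = self.barcode_span
        recs = []
        for sid, row in self.aligned_rows.items():
            recs.append(SequenceRecord(sid, row[lo - 1:hi],
                                       species=self.samples[sid],
                                       group=self.species_groups[self.samples[sid]]))
        return Alignment(recs)

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["config"] = asdict(self.config)
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _draw_ancestor(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Ancestral 301-column frame: barcode at gc_target composition, flanks at
    50% GC, with all planted landing sites and motifs written on top."""
    L = 2 * cfg.flank_length + cfg.barcode_length
    gc_b = cfg.gc_target
    seq = np.empty(L, dtype="<U1")
    p_flank = [0.25, 0.25, 0.25, 0.25]
    p_bar = [(1 - gc_b) / 2, gc_b / 2, gc_b / 2, (1 - gc_b) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    seq[: _FLANK] = rng.choice(bases, size=_FLANK, p=p_flank)
    seq[_FLANK:_FLANK + cfg.barcode_length] = rng.choice(
        bases, size=cfg.barcode_length, p=p_bar)
    seq[_FLANK + cfg.barcode_length:] = rng.choice(bases, size=_FLANK, p=p_flank)

    def write(start: int, text: str) -> None:
        seq[start - 1:start - 1 + len(text)] = list(text)

    write(_FWD_FOOTPRINT[0], ITS2F.sequence)
    # reverse footprint: random but fixed landing site (kept conserved later)
    # diagnostic motif: GCC NNNNN GG + ancestral A (no site; target completes it)
    write(_DIAG_MOTIF[0], "GCC")
    write(_DIAG_MOTIF[0] + 8, "GGA")
    # confounding, complete Bgl I site inside the reverse footprint
    write(_CONF_MOTIF[0], "GCC")
    write(_CONF_MOTIF[0] + 8, "GGC")
    return seq


def _protected_positions() -> frozenset[int]:
    prot: set[int] = set()
    for lo, hi in (_FWD_FOOTPRINT, _REV_FOOTPRINT, _DIAG_MOTIF, _CONF_MOTIF):
        prot.update(range(lo, hi + 1))
    prot.add(_DIAG_INDEL)
    prot.add(_DIAG_SUB)
    return frozenset(prot)


def _substitute(row: np.ndarray, positions: np.ndarray, rng: np.random.Generator,
                kappa: float) -> None:
    """Apply one substitution at each 1-based position (in place), choosing a
    transition with probability kappa/(kappa+2)."""
    p_ts = kappa / (kappa + 2.0)
    for pos in positions:
        old = row[pos - 1]
        if old == "-":
            continue
        if rng.random() < p_ts:
            row[pos - 1] = _TRANSITION[old]
        else:
            row[pos - 1] = _TRANSVERSIONS[old][rng.integers(0, 2)]


def _purge_unplanted_sites(row: np.ndarray, enzyme: Enzyme, free: np.ndarray) -> None:
    """Destroy restriction sites that arose by chance outside the planted
    coordinates, by mutating one free, motif-defined base of each hit.

    The fix is deterministic (first free defined base, first transversion), so
    every sequence sharing the same chance hit receives the identical repair
    and no artificial polymorphism is introduced."""
    planted_starts = {_DIAG_MOTIF[0], _CONF_MOTIF[0]}
    free_set = set(int(p) for p in free)
    for _ in range(10):
        seq = "".join(c for c in row if c != "-")
        # map ungapped coordinates back to frame coordinates
        frame_of = [i + 1 for i, c in enumerate(row) if c != "-"]
        hits = find_motif_sites(seq, enzyme, both_strands=True)
        bad = [h for h in hits if frame_of[h[0] - 1] not in planted_starts]
        if not bad:
            return
        for start, _strand in bad:
            defined = [k for k, sym in enumerate(enzyme.motif) if sym in "ACGT"]
            cands = [frame_of[start - 1 + k] for k in defined
                     if frame_of[start - 1 + k] in free_set]
            if not cands:
                continue
            pos = cands[0]
            old = row[pos - 1]
            row[pos - 1] = _TRANSVERSIONS[old][0]


def simulate_library(config: SyntheticConfig
                     ) -> tuple[list[SequenceRecord], SampleTable, TruthLedger]:
    """Generate the reference library, its metadata table and the truth ledger.

    Returns ungapped full-template records (primer flanks included); the true
    barcode alignment is available from the ledger.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = 2 * cfg.flank_length + cfg.barcode_length
    ancestor = _draw_ancestor(rng, cfg)
    prot = _protected_positions()
    free = np.array(sorted(set(range(1, L + 1)) - prot))
    _purge_unplanted_sites(ancestor, BGL_I, free)

    # species ancestors ------------------------------------------------------
    # the target genus gets a stem edge (shared derived states uniting the
    # target and its congeners against the distant adulterants), mirroring a
    # genus that radiated long after splitting from the outgroups
    genus_anc = ancestor.copy()
    n_stem = max(1, round(cfg.genus_stem_divergence * free.size))
    _substitute(genus_anc, rng.choice(free, size=n_stem, replace=False), rng, cfg.kappa)
    _purge_unplanted_sites(genus_anc, BGL_I, free)

    target = "target_species"
    species_rows: dict[str, np.ndarray] = {}
    species_groups: dict[str, str] = {target: "target"}
    species_div: dict[str, float] = {target: 0.0}

    tgt_row = genus_anc.copy()
    tgt_row[_DIAG_INDEL - 1] = "-"
    tgt_row[_DIAG_SUB - 1] = "C"  # completes the planted Bgl I site
    species_rows[target] = tgt_row

    factors = np.linspace(0.5, 2.5, cfg.n_congener_species)
    for i in range(cfg.n_congener_species):
        sp = f"congener_{i + 1:02d}"
        d = float(factors[i] * cfg.congener_divergence)
        n_sub = max(1, round(d * free.size))
        row = genus_anc.copy()
        pos = rng.choice(free, size=n_sub, replace=False)
        _substitute(row, pos, rng, cfg.kappa)
        _purge_unplanted_sites(row, BGL_I, free)
        species_rows[sp] = row
        species_groups[sp] = "congener"
        species_div[sp] = d
    for j in range(cfg.n_adulterant_species):
        sp = f"adulterant_{j + 1:02d}"
        d = cfg.adulterant_divergence
        n_sub = max(1, round(d * free.size))
        row = ancestor.copy()
        pos = rng.choice(free, size=n_sub, replace=False)
        _substitute(row, pos, rng, cfg.kappa)
        # disrupt the reverse primer's 3'-clamp landing so the specific pair
        # cannot amplify (the clamp sits at frame positions 280-282)
        for p in range(_REV_FOOTPRINT[0], _REV_FOOTPRINT[0] + 3):
            row[p - 1] = _TRANSITION[str(row[p - 1])]
        _purge_unplanted_sites(row, BGL_I, free)
        species_rows[sp] = row
        species_groups[sp] = "adulterant"
        species_div[sp] = d

    # samples ----------------------------------------------------------------
    records: list[SequenceRecord] = []
    samples: dict[str, str] = {}
    aligned_rows: dict[str, str] = {}
    meta_rows = []
    for sp in species_rows:
        anc = species_rows[sp]
        for k in range(cfg.samples_per_species):
            sid = f"{sp}.s{k + 1}"
            row = anc.copy()
            n_priv = rng.poisson(cfg.intra_subs)
            if n_priv:
                pos = rng.choice(free, size=min(n_priv, free.size), replace=False)
                _substitute(row, pos, rng, cfg.kappa)
            _purge_unplanted_sites(row, BGL_I, free)
            aligned_rows[sid] = "".join(row)
            samples[sid] = sp
            records.append(SequenceRecord(sid, "".join(c for c in row if c != "-"),
                                          species=sp, group=species_groups[sp]))
            meta_rows.append({"sample_id": sid, "species": sp,
                              "group": species_groups[sp], "accession": ""})
    table = SampleTable(pd.DataFrame(meta_rows))

    # primers & expectations -------------------------------------------------
    lo, hi = _REV_FOOTPRINT
    tgt_template = "".join(c for c in tgt_row if c != "-")
    # the deletion sits 5' of the footprint, so target coordinates are -1
    rev_base = reverse_complement(tgt_template[lo - 2:hi - 1])
    k = _ENGINEERED_PRIMER_POS - 1
    assert rev_base[k] == "G", "layout error: engineered position is not a G"
    rev_eng = rev_base[:k] + "T" + rev_base[k + 1:]

    bar_lo = _BARCODE[0]
    truth = TruthLedger(
        config=cfg,
        template_length=L,
        barcode_span=_BARCODE,
        samples=samples,
        species_groups=species_groups,
        species_divergence=species_div,
        aligned_rows=aligned_rows,
        diagnostic_sites_barcode=[
            {"position": _DIAG_INDEL - bar_lo + 1, "state": "-"},
            {"position": _DIAG_SUB - bar_lo + 1, "state": "C"},
        ],
        fwd_primer=ITS2F.sequence,
        rev_primer_base=rev_base,
        rev_primer_engineered=rev_eng,
        rev_footprint=_REV_FOOTPRINT,
        rev_footprint_template=(lo - 1, hi - 1),
        engineered_position=_ENGINEERED_PRIMER_POS,
        enzyme=BGL_I.name,
        target_species=target,
        expected_amplicon_length=292,
        expected_fragments=(168, 124),
    )
    return records, table, truth


def default_composition(truth: TruthLedger) -> dict[str, int]:
    """A 29-product market-survey mix: 2 target, 12 congeneric substitutes,
    15 distant contaminants (a mixture product can be added on top)."""
    comp = {truth.target_species: 2,
            "congener_01": 9, "congener_02": 2, "congener_03": 1,
            "adulterant_01": 8, "adulterant_02": 3, "adulterant_03": 2,
            "adulterant_04": 1, "adulterant_05": 1}
    known = set(truth.species_groups)
    return {sp: n for sp, n in comp.items() if sp in known}


def simulate_products(records: Sequence[SequenceRecord], truth: TruthLedger,
                      composition: Mapping[str, int], seed: int = 1, *,
                      intra_subs: float | None = None,
                      mixture: bool = False,
                      mixture_species: tuple[str, str] | None = None,
                      ) -> tuple[list[SequenceRecord], dict[str, str], dict[str, str]]:
    """Simulate commercial-product query sequences.

    Each product draws a random conspecific library sample and adds
    Poisson(intra_subs) private substitutions (planted features stay
    protected).  With ``mixture=True`` one extra product carries two records
    from two species under a single product id.  Returns
    (query records, sequence_id -> product_id, sequence_id -> true species).
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    rate = cfg.intra_subs if intra_subs is None else intra_subs
    prot = _protected_positions()
    free = np.array(sorted(set(range(1, truth.template_length + 1)) - prot))
    by_species: dict[str, list[str]] = {}
    for sid, sp in truth.samples.items():
        by_species.setdefault(sp, []).append(sid)
    unknown = [sp for sp in composition if sp not in by_species]
    if unknown:
        raise ValueError(f"composition species not in library: {unknown}")

    queries: list[SequenceRecord] = []
    products: dict[str, str] = {}
    true_species: dict[str, str] = {}
    n = 0

    def one_sequence(sp: str, seq_id: str) -> SequenceRecord:
        src = by_species[sp][rng.integers(0, len(by_species[sp]))]
        row = np.array(list(truth.aligned_rows[src]), dtype="<U1")
        n_priv = rng.poisson(rate)
        if n_priv:
            pos = rng.choice(free, size=min(n_priv, free.size), replace=False)
            _substitute(row, pos, rng, cfg.kappa)
        _purge_unplanted_sites(row, BGL_I, free)
        return SequenceRecord(seq_id, "".join(c for c in row if c != "-"),
                              species="", group="query")

    for sp, count in composition.items():
        for _ in range(count):
            n += 1
            pid = f"Y{n}"
            rec = one_sequence(sp, pid)
            queries.append(rec)
            products[pid] = pid
            true_species[pid] = sp
    if mixture:
        n += 1
        pid = f"Y{n}"
        if mixture_species is None:
            labels = list(composition) or list(by_species)
            mixture_species = (labels[0], labels[-1])
        for tag, sp in zip("ab", mixture_species):
            sid = f"{pid}{tag}"
            rec = one_sequence(sp, sid)
            queries.append(rec)
            products[sid] = pid
            true_species[sid] = sp
    return queries, products, true_species
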