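"""In-silico PCR-RFLP assay design.

Pieces: degenerate restriction-motif scanning, primer-binding search with a
mismatch budget and a strict 3'-clamp, amplicon prediction with primer regions
overwritten by primer bases (what the physical product contains — essential
when a primer is mismatch-engineered), digestion into fragment patterns,
per-species differential digestion, and mismatch engineering of a primer so
that a confounding restriction site disappears from every product.

Conventions: coordinates are 1-based inclusive on the plus strand; an
amplicon runs from the forward primer's first base to the reverse primer
footprint's last base.  A degenerate template base never satisfies an enzyme
motif (a site must be certain to be cut) but counts as an ordinary mismatch
for primer binding.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import IUPAC_SETS, SampleTable, reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "Enzyme",
    "BGL_I",
    "Primer",
    "PrimerBinding",
    "Amplicon",
    "DigestPattern",
    "SpeciesPrediction",
    "AssayDesign",
    "PcrConstraints",
    "find_motif_sites",
    "digest",
    "find_primer_sites",
    "in_silico_pcr",
    "differential_digestion",
    "engineer_primer",
    "select_assay",
    "gel_schematic",
]


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC motif and top-strand cut offset (cut falls
    after ``cut_offset`` motif bases)."""

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not all(c in IUPAC_SETS for c in self.motif):
            raise ValueError(f"motif {self.motif!r} must be IUPAC letters")
        if not 1 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut_offset must lie within the motif")


#: Bgl I: GCCNNNN^NGGC (3-nt 3' overhang; top-strand cut after base 7).
BGL_I = Enzyme(name="BglI", motif="GCCNNNNNGGC", cut_offset=7)


@dataclass(frozen=True)
class Primer:
    """PCR primer, written 5'->3'; unambiguous bases only."""

    name: str
    sequence: str
    role: str  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError("primer must be >= 10 bases")
        if not set(seq) <= set("ACGT"):
            raise ValueError("primer must contain unambiguous A/C/G/T only")
        if self.role not in ("forward", "reverse"):
            raise ValueError("role must be 'forward' or 'reverse'")


# Shipped primers: the universal ITS2 amplification pair and the
# species-specific reverse primer whose 13th base (5'-counted) carries the
# engineered G->T substitution relative to the template-matching sequence.
ITS2F = Primer("ITS2F", "ATGCGATACTTGGTGTGAAT", "forward")
ITS3R = Primer("ITS3R", "GACGCTTCTCCAGACTACAAT", "reverse")
PR1 = Primer("PR1", "TGGGTCATCTTCTCCCAGC", "reverse")


@dataclass(frozen=True)
class PrimerBinding:
    template_id: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive, plus strand
    end: int
    mismatches: int
    three_prime_clamp_ok: bool = True


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    product: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DigestPattern:
    fragments: tuple[int, ...]
    cuts: tuple[int, ...]  # 1-based positions after which the top strand is cut


@dataclass(frozen=True)
class PcrConstraints:
    max_mismatch: int = 1
    clamp: int = 3
    min_len: int = 50
    max_len: int = 2000


def _iupac_match(template_base: str, motif_sym: str) -> bool:
    # template base must itself be unambiguous for a certain match
    if template_base not in "ACGT":
        return False
    return template_base in IUPAC_SETS[motif_sym]


def find_motif_sites(residues: str, enzyme: Enzyme, both_strands: bool = True
                     ) -> list[tuple[int, str]]:
    """All (1-based start, strand) where the motif matches with certainty.

    Minus-strand duplicates of plus-strand hits (palindromic motifs) are
    deduplicated by plus-strand footprint.
    """
    seq = residues.upper()
    if "-" in seq:
        raise ValueError("find_motif_sites expects ungapped input")
    motif = enzyme.motif
    m, L = len(motif), len(seq)
    hits: list[tuple[int, str]] = []
    for i in range(L - m + 1):
        if all(_iupac_match(seq[i + k], motif[k]) for k in range(m)):
            hits.append((i + 1, "+"))
    if both_strands:
        plus_starts = {h[0] for h in hits}
        rc = reverse_complement(seq)
        for i in range(L - m + 1):
            if all(_iupac_match(rc[i + k], motif[k]) for k in range(m)):
                start = L - (i + m) + 1  # plus-strand footprint start
                if start not in plus_starts:
                    hits.append((start, "-"))
    return sorted(hits)


def digest(amplicon: Amplicon, enzyme: Enzyme) -> DigestPattern:
    """Fragment lengths (template order) after cutting at every motif hit.

    Cuts are top-strand, linear molecule: for a plus-strand hit starting at
    product position p, the cut falls after base p + cut_offset - 1.
    """
    product = amplicon.product
    hits = find_motif_sites(product, enzyme, both_strands=True)
    cuts = sorted({p + enzyme.cut_offset - 1 for p, _strand in hits})
    cuts = [c for c in cuts if 1 <= c < len(product)]
    frags: list[int] = []
    prev = 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(product) - prev)
    return DigestPattern(fragments=tuple(frags), cuts=tuple(cuts))


def _mismatches(window: str, primer_seq: str, clamp: int) -> tuple[int, bool]:
    """Mismatch count of primer vs template window (both 5'->3' of the primer);
    degenerate template bases count as mismatches.  Clamp requires the 3'-most
    ``clamp`` primer bases to match exactly."""
    mm = 0
    clamp_ok = True
    m = len(primer_seq)
    for k in range(m):
        ok = window[k] == primer_seq[k] and window[k] in "ACGT"
        if not ok:
            mm += 1
            if k >= m - clamp:
                clamp_ok = False
    return mm, clamp_ok


def find_primer_sites(template: str, primer: Primer, max_mismatch: int = 1,
                      clamp: int = 3, template_id: str = "") -> list[PrimerBinding]:
    """Binding sites of ``primer`` on a plus-strand template.

    Forward primers are scanned against the plus strand, reverse primers
    against the minus strand (via reverse complement).  A binding needs
    <= ``max_mismatch`` mismatches overall and zero in the 3'-terminal
    ``clamp`` bases.
    """
    seq = template.upper()
    if "-" in seq:
        raise ValueError("find_primer_sites expects ungapped input")
    m, L = len(primer.sequence), len(seq)
    if m > L:
        return []
    scan = seq if primer.role == "forward" else reverse_complement(seq)
    out: list[PrimerBinding] = []
    for i in range(L - m + 1):
        mm, clamp_ok = _mismatches(scan[i:i + m], primer.sequence, clamp)
        if mm <= max_mismatch and clamp_ok:
            if primer.role == "forward":
                start = i + 1
            else:
                start = L - (i + m) + 1
            out.append(PrimerBinding(template_id=template_id,
                                     strand="+" if primer.role == "forward" else "-",
                                     start=start, end=start + m - 1, mismatches=mm))
    return sorted(out, key=lambda b: b.start)


def in_silico_pcr(template: str, fwd: Primer, rev: Primer,
                  constraints: PcrConstraints = PcrConstraints(),
                  template_id: str = "") -> list[Amplicon]:
    """All products of a forward x reverse binding pair within the length
    bounds.  The product sequence carries the primer bases verbatim (the
    reverse primer as its reverse complement) over the primer footprints."""
    seq = template.upper()
    f_sites = find_primer_sites(seq, fwd, constraints.max_mismatch, constraints.clamp,
                                template_id)
    r_sites = find_primer_sites(seq, rev, constraints.max_mismatch, constraints.clamp,
                                template_id)
    out: list[Amplicon] = []
    for fb in f_sites:
        for rb in r_sites:
            if fb.start >= rb.start:
                continue
            length = rb.end - fb.start + 1
            if not constraints.min_len <= length <= constraints.max_len:
                continue
            if fb.end >= rb.start:  # overlapping footprints: not a product
                continue
            core = seq[fb.end:rb.start - 1]
            product = fwd.sequence + core + reverse_complement(rev.sequence)
            out.append(Amplicon(template_id=template_id, start=fb.start, end=rb.end,
                                product=product))
    return out


@dataclass
class SpeciesPrediction:
    amplifies: bool
    pattern: DigestPattern | None
    ambiguous: bool = False

    @property
    def cut(self) -> bool:
        return self.pattern is not None and len(self.pattern.fragments) > 1


@dataclass
class AssayDesign:
    fwd: Primer
    rev: Primer
    enzyme: Enzyme
    per_species: dict[str, SpeciesPrediction]
    per_sample: dict[str, SpeciesPrediction] = field(default_factory=dict)
    target: str = ""
    engineered: bool = False
    n_substitutions: int = 0

    @property
    def discriminates(self) -> bool:
        """True iff the target is uniquely (amplified AND cut)."""
        if self.target not in self.per_species:
            return False
        tgt = self.per_species[self.target]
        if not (tgt.amplifies and tgt.cut) or tgt.ambiguous:
            return False
        return all(
            not (p.amplifies and p.cut)
            for sp, p in self.per_species.items()
            if sp != self.target
        )

    def min_fragment_gap(self) -> int:
        """Smallest absolute difference between target fragment lengths and any
        cut non-target's (used only for ranking; 0 when no cut non-target)."""
        tgt = self.per_species.get(self.target)
        if tgt is None or tgt.pattern is None:
            return 0
        gaps = []
        for sp, p in self.per_species.items():
            if sp == self.target or p.pattern is None:
                continue
            for a in tgt.pattern.fragments:
                for b in p.pattern.fragments:
                    gaps.append(abs(a - b))
        return min(gaps) if gaps else min(tgt.pattern.fragments)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "forward_primer": {"name": self.fwd.name, "sequence": self.fwd.sequence},
            "reverse_primer": {"name": self.rev.name, "sequence": self.rev.sequence},
            "enzyme": {"name": self.enzyme.name, "motif": self.enzyme.motif,
                       "cut_offset": self.enzyme.cut_offset},
            "target": self.target,
            "engineered": self.engineered,
            "n_substitutions": self.n_substitutions,
            "discriminates": self.discriminates,
            "per_species": {
                sp: {
                    "amplifies": p.amplifies,
                    "fragments": list(p.pattern.fragments) if p.pattern else None,
                    "ambiguous": p.ambiguous,
                }
                for sp, p in self.per_species.items()
            },
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _predict_sample(template: str, fwd: Primer, rev: Primer, enzyme: Enzyme,
                    constraints: PcrConstraints, template_id: str = "") -> SpeciesPrediction:
    amps = in_silico_pcr(template, fwd, rev, constraints, template_id)
    if not amps:
        return SpeciesPrediction(amplifies=False, pattern=None)
    # all products reported; the digest pattern of the first (5'-most) product
    # is used for the species readout, discordance across products is flagged
    patterns = [digest(a, enzyme) for a in amps]
    ambiguous = len({p.fragments for p in patterns}) > 1
    return SpeciesPrediction(amplifies=True, pattern=patterns[0], ambiguous=ambiguous)


def differential_digestion(library: Mapping[str, str], table: SampleTable,
                           fwd: Primer, rev: Primer, enzyme: Enzyme,
                           constraints: PcrConstraints = PcrConstraints(),
                           target: str = "") -> AssayDesign:
    """Predict amplification + digestion for every sample and summarize per
    species (consensus; discordant samples flag the species ambiguous)."""
    if not library:
        raise ValueError("library must be non-empty")
    species_labels = [s for s in table.species_labels()
                      if any(i in library for i in table.members(s))]
    if len(species_labels) < 2:
        raise ValueError("differential digestion needs >= 2 species")
    per_sample: dict[str, SpeciesPrediction] = {}
    per_species: dict[str, SpeciesPrediction] = {}
    for sp in species_labels:
        preds = []
        for sid in table.members(sp):
            if sid not in library:
                continue
            p = _predict_sample(library[sid], fwd, rev, enzyme, constraints, sid)
            per_sample[sid] = p
            preds.append(p)
        keys = {(p.amplifies, p.pattern.fragments if p.pattern else None) for p in preds}
        consensus = preds[0]
        if len(keys) > 1:
            log.warning("species %s: discordant assay predictions across samples", sp)
            consensus = SpeciesPrediction(amplifies=any(p.amplifies for p in preds),
                                          pattern=consensus.pattern, ambiguous=True)
        per_species[sp] = consensus
    return AssayDesign(fwd=fwd, rev=rev, enzyme=enzyme, per_species=per_species,
                       per_sample=per_sample, target=target)


def _footprint_primer(reference: str, footprint: tuple[int, int], name: str) -> Primer:
    """Reverse primer matching the reference's plus-strand ``footprint`` exactly."""
    start, end = footprint
    return Primer(name, reverse_complement(reference[start - 1:end]), "reverse")


def engineer_primer(templates: Mapping[str, str], footprint: tuple[int, int],
                    enzyme: Enzyme, budget: int = 1, *,
                    reference: str | None = None,
                    fwd: Primer = ITS2F,
                    constraints: PcrConstraints = PcrConstraints(),
                    name: str = "engineered") -> tuple[list[Primer], dict[str, int]]:
    """Substitution-engineer a reverse primer so every species' product loses
    all enzyme sites overlapping the reverse-primer footprint.

    ``footprint`` is a plus-strand interval on ``reference`` (default: the
    first template); the unengineered primer is its reverse complement.
    Candidates with up to ``budget`` substitutions are accepted when, for every
    template, (i) the product carries no enzyme site overlapping the primer
    region, (ii) binding stays within the mismatch budget with the 3'-clamp
    intact, and (iii) no enzyme site anywhere in any product is newly created
    relative to that product's pre-existing, non-footprint sites.  Proposals
    are ranked by fewest substitutions, then substitutions far from the 3' end
    first.  Returns (proposals, per-constraint failure tally).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    ref = reference if reference is not None else next(iter(templates.values()))
    base = _footprint_primer(ref, footprint, name)
    m = len(base.sequence)

    def products(primer: Primer) -> dict[str, list[Amplicon]]:
        return {sp: in_silico_pcr(t, fwd, primer, constraints, sp)
                for sp, t in templates.items()}

    def footprint_sites(amp: Amplicon) -> list[tuple[int, str]]:
        lo = amp.length - m + 1  # product positions covered by the reverse primer
        return [h for h in find_motif_sites(amp.product, enzyme)
                if h[0] + len(enzyme.motif) - 1 >= lo]

    base_products = products(base)
    if any(not amps for amps in base_products.values()):
        missing = [sp for sp, amps in base_products.items() if not amps]
        raise ValueError(f"footprint primer fails to amplify template(s): {missing}")
    if all(not footprint_sites(a) for amps in base_products.values() for a in amps):
        return [base], {}
    baseline_outside = {
        sp: {h for a in amps for h in find_motif_sites(a.product, enzyme)
             if h not in footprint_sites(a)}
        for sp, amps in base_products.items()
    }

    tally = {"no_amplification": 0, "clamp": 0, "footprint_site_remains": 0,
             "new_site_created": 0}
    proposals: list[tuple[int, int, Primer]] = []
    positions = list(range(m))  # 0-based primer positions, 5'->3'
    for n_sub in range(1, budget + 1):
        for combo in itertools.combinations(positions, n_sub):
            if any(p >= m - constraints.clamp for p in combo):
                tally["clamp"] += 1
                continue
            for repl in itertools.product("ACGT", repeat=n_sub):
                if any(base.sequence[p] == r for p, r in zip(combo, repl)):
                    continue
                seq = list(base.sequence)
                for p, r in zip(combo, repl):
                    seq[p] = r
                cand = Primer(f"{name}_{n_sub}sub", "".join(seq), "reverse")
                cand_products = products(cand)
                if any(not amps for amps in cand_products.values()):
                    tally["no_amplification"] += 1
                    continue
                ok = True
                for sp, amps in cand_products.items():
                    for a in amps:
                        fps = footprint_sites(a)
                        if fps:
                            tally["footprint_site_remains"] += 1
                            ok = False
                            break
                        extra = {h for h in find_motif_sites(a.product, enzyme)} \
                            - baseline_outside[sp]
                        if extra:
                            tally["new_site_created"] += 1
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    dist3 = min(m - 1 - p for p in combo)
                    proposals.append((n_sub, -dist3, cand))
    proposals.sort(key=lambda t: (t[0], t[1], t[2].sequence))
    return [p for _, _, p in proposals], tally


def select_assay(templates: Mapping[str, str], table: SampleTable, target: str,
                 enzymes: Sequence[Enzyme],
                 rev_footprints: Sequence[tuple[int, int]],
                 *, fwd: Primer = ITS2F,
                 constraints: PcrConstraints = PcrConstraints(),
                 diagnostic_positions: Sequence[int] | None = None,
                 budget: int = 1) -> list[AssayDesign]:
    """Rank candidate PCR-RFLP designs for ``target``.

    For every enzyme x reverse footprint (a plus-strand interval on the
    target's template): build the footprint-matching reverse primer, predict
    differential digestion, and — when the target is not uniquely (amplified
    AND cut) because other species' products also carry sites — attempt primer
    engineering.  Designs where the target's cut overlaps a supplied
    diagnostic position are preferred; ranking is clean designs first, then
    engineered by substitution count, then larger minimum fragment-size
    separation.  Returns a ranked (possibly empty) list.
    """
    tgt_ids = [i for i in table.members(target) if i in templates]
    if not tgt_ids:
        raise ValueError(f"target {target!r} has no templates")
    reference = templates[tgt_ids[0]]
    species_templates = {}
    for sp in table.species_labels():
        ids = [i for i in table.members(sp) if i in templates]
        if ids:
            species_templates[sp] = templates[ids[0]]

    designs: list[tuple[tuple, AssayDesign]] = []
    for enzyme in enzymes:
        for fp in rev_footprints:
            try:
                base_rev = _footprint_primer(reference, fp, f"rev_{fp[0]}_{fp[1]}")
            except ValueError:
                continue
            design = differential_digestion(templates, table, fwd, base_rev, enzyme,
                                            constraints, target)
            candidates: list[tuple[bool, int, AssayDesign]] = []
            if design.discriminates:
                candidates.append((False, 0, design))
            else:
                amplifying = {sp: t for sp, t in species_templates.items()
                              if in_silico_pcr(t, fwd, base_rev, constraints)}
                if target in amplifying:
                    try:
                        proposals, _tally = engineer_primer(
                            amplifying, fp, enzyme, budget, reference=reference,
                            fwd=fwd, constraints=constraints, name=base_rev.name)
                    except ValueError:
                        proposals = []
                    for prop in proposals[:3]:
                        n_sub = sum(a != b for a, b in zip(prop.sequence, base_rev.sequence))
                        d2 = differential_digestion(templates, table, fwd, prop, enzyme,
                                                    constraints, target)
                        d2.engineered = n_sub > 0
                        d2.n_substitutions = n_sub
                        if d2.discriminates:
                            candidates.append((n_sub > 0, n_sub, d2))
                            break
            for engineered, n_sub, d in candidates:
                tgt_pred = d.per_species.get(target)
                diag_hit = 0
                if diagnostic_positions and tgt_pred and tgt_pred.pattern:
                    # map product cuts back onto the template positions
                    amp = in_silico_pcr(reference, fwd, d.rev, constraints)
                    if amp:
                        start = amp[0].start
                        cut_positions = {start + c - 1 for c in tgt_pred.pattern.cuts}
                        motif_span = max(len(e.motif) for e in enzymes)
                        diag_hit = -sum(
                            any(abs(cp - dp) <= motif_span for cp in cut_positions)
                            for dp in diagnostic_positions
                        )
                key = (int(engineered), n_sub, diag_hit, -d.min_fragment_gap())
                designs.append((key, d))
    designs.sort(key=lambda t: t[0])
    return [d for _, d in designs]


def gel_schematic(design: AssayDesign) -> str:
    """Text table of species x predicted fragment lengths (gel mock-up)."""
    lines = [f"{'species':<28} amplifies  fragments"]
    for sp, p in design.per_species.items():
        frag = "-" if p.pattern is None else "+".join(str(f) for f in p.pattern.fragments)
        amp = "+" if p.amplifies else "-"
        flag = " (ambiguous)" if p.ambiguous else ""
        lines.append(f"{sp:<28} {amp:^9}  {frag}{flag}")
    return "\n".join(lines)
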