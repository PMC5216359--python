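"""Diagnostic character mining: alignment columns whose state is fixed in the
target species and absent from a comparison scope.

A column qualifies when (i) every target sequence carries the same unambiguous
state x in {A, C, G, T, -} and (ii) x is not observed in any scope sequence at
that column.  Ambiguity codes in the scope disqualify a column conservatively
whenever they could encode x.  A single-nucleotide indel is a diagnostic state
like any other; a multi-column indel yields one site per column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqio import IUPAC_SETS, Alignment, SampleTable
from .stats import collapse_haplotypes, variable_sites

__all__ = [
    "DiagnosticSite",
    "SiteCheck",
    "diagnostic_sites",
    "count_polymorphic_sites",
    "check_query_diagnostics",
    "write_diagnostic_report",
]


@dataclass(frozen=True)
class DiagnosticSite:
    """A 1-based alignment column fixed in the target and absent elsewhere."""

    position: int
    target_state: str
    other_states: frozenset[str]
    frame: str = "library"

    def __post_init__(self) -> None:
        if self.target_state in self.other_states:
            raise ValueError("target state observed outside the target")


def _could_encode(code: str, state: str) -> bool:
    """True if IUPAC ``code`` could stand for unambiguous ``state``."""
    if code == state:
        return True
    if code == "-" or state == "-":
        return False
    return state in IUPAC_SETS.get(code, frozenset())


def diagnostic_sites(alignment: Alignment, table: SampleTable, target: str,
                     scope: Iterable[str] | None = None, *,
                     min_target_fraction: float = 1.0,
                     frame: str = "library") -> list[DiagnosticSite]:
    """Mine columns diagnostic for ``target`` against ``scope`` species.

    ``scope`` defaults to every other species in the table.  With the default
    ``min_target_fraction=1.0`` the target must be strictly monomorphic at a
    reported column; lower values relax condition (i) to "x fixed in at least
    that fraction of target sequences" while (ii) stays strict.
    """
    target_ids = [i for i in table.members(target) if i in set(alignment.ids())]
    if not target_ids:
        raise ValueError(f"target {target!r} absent from alignment")
    if scope is None:
        scope_species = set(table.species_labels()) - {target}
    else:
        scope_species = set(scope) - {target}
    if not scope_species:
        raise ValueError("comparison scope is empty")
    scope_ids = [i for i in table.members(scope_species) if i in set(alignment.ids())]
    if not scope_ids:
        raise ValueError(f"scope species {sorted(scope_species)} absent from alignment")
    tgt = alignment.subset(target_ids)
    scp = alignment.subset(scope_ids)
    out: list[DiagnosticSite] = []
    for pos in range(1, alignment.length + 1):
        t_states = list(tgt.column(pos))
        best, best_n = None, 0
        for cand in "ACGT-":
            n = t_states.count(cand)
            if n > best_n:
                best, best_n = cand, n
        if best is None or best_n < min_target_fraction * len(t_states):
            continue
        if min_target_fraction >= 1.0 and best_n < len(t_states):
            continue
        s_states = set(scp.column(pos))
        if any(_could_encode(s, best) for s in s_states):
            continue
        out.append(DiagnosticSite(position=pos, target_state=best,
                                  other_states=frozenset(s_states), frame=frame))
    return out


def count_polymorphic_sites(alignment: Alignment, members: Iterable[str] | None = None) -> int:
    """Number of variable columns among the distinct haplotypes of ``members``."""
    ids = list(members) if members is not None else alignment.ids()
    if len(ids) < 2:
        raise ValueError("need at least 2 members")
    haps = collapse_haplotypes(alignment, ids)
    if len(haps) < 2:
        return 0
    return len(variable_sites(alignment, haps.representative_ids()))


@dataclass(frozen=True)
class SiteCheck:
    """Outcome of testing one diagnostic site on an aligned query."""

    site: DiagnosticSite
    observed: str
    match: bool


def check_query_diagnostics(query: str, sites: Sequence[DiagnosticSite]
                            ) -> tuple[list[SiteCheck], bool]:
    """Test an aligned query (same coordinate frame as the library alignment)
    against each diagnostic site; verdict is all-match."""
    checks: list[SiteCheck] = []
    for site in sites:
        if not 1 <= site.position <= len(query):
            raise IndexError(f"site position {site.position} outside query of length {len(query)}")
        obs = query[site.position - 1]
        checks.append(SiteCheck(site=site, observed=obs, match=obs == site.target_state))
    return checks, all(c.match for c in checks)


def write_diagnostic_report(sites: Sequence[DiagnosticSite], path: str | Path) -> None:
    rows = [
        {
            "position": s.position,
            "frame": s.frame,
            "target_state": s.target_state,
            "other_states": ",".join(sorted(s.other_states)),
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=["position", "frame", "target_state", "other_states"]).to_csv(
        path, sep="\t", index=False
    )
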