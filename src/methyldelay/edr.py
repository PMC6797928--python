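"""Epigenetically dynamic regions: CpGs that are both inside a bivalent
chromatin domain and developmentally dynamic in fetal brain, and the
enrichment of case-associated DML within them.

"DML associated with the condition" is taken as the union of probe ids
across the per-age-group DML sets; a different denominator can be passed
explicitly.
"""

from __future__ import annotations

import dataclasses

from .regions import EnrichmentResult, fold_enrichment


@dataclasses.dataclass
class EDRSet:
    probe_ids: frozenset
    bivalent_source: str = ""
    dynamic_source: str = ""

    def __len__(self) -> int:
        return len(self.probe_ids)


def define_edr(
    bivalent_probes,
    dynamic_probes,
    bivalent_source: str = "",
    dynamic_source: str = "",
) -> EDRSet:
    """Intersection of the bivalent and dynamic probe sets."""
    return EDRSet(
        probe_ids=frozenset(bivalent_probes) & frozenset(dynamic_probes),
        bivalent_source=bivalent_source,
        dynamic_source=dynamic_source,
    )


def dynamic_overlap(dml_union, dynamic_probes, background) -> EnrichmentResult:
    """Enrichment of DML among developmentally dynamic CpGs vs the
    retained-probe background."""
    dml = set(dml_union)
    dynamic = set(dynamic_probes)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    return fold_enrichment(
        n_in_subset=len(dml & dynamic),
        n_subset=len(dml),
        n_in_background=len(bg & dynamic),
        n_background=len(bg),
    )


def edr_enrichment(dml_union, edr: EDRSet, background) -> EnrichmentResult:
    """Enrichment of DML within EDRs vs the retained-probe background."""
    dml = set(dml_union)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    return fold_enrichment(
        n_in_subset=len(dml & edr.probe_ids),
        n_subset=len(dml),
        n_in_background=len(bg & edr.probe_ids),
        n_background=len(bg),
    )


def dml_union(dml_sets) -> set:
    """Union of probe ids over DMLSet objects or plain id collections."""
    out: set = set()
    for item in dml_sets:
        out |= set(getattr(item, "probe_ids", item))
    return out
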