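"""Per-clade prevalence and motif-composition rollups.

Produces the survey-style reporting tables: for each taxogroup, how many
searched species have at least one surviving clustered GH99 record, and the
residue composition at a motif position (e.g. W/Y/L at 189) among records
from the clade.  Undetermined calls (``?``, from partial sequences) are
reported separately and excluded from percentage denominators.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import AnnotationResult
from .cluster import ClusterAssignment
from .motifs import MOTIF_SPANS
from .seqio import ProteinRecord, TaxonomyTable

__all__ = ["presence_absence", "residue_composition", "composition_table"]


def presence_absence(
    assignment: ClusterAssignment,
    records_by_id: Mapping[str, ProteinRecord],
    tax: TaxonomyTable,
    clades: Sequence[str],
) -> pd.DataFrame:
    """Per-clade species-level presence table after clustering.

    A species counts once no matter how many records or clusters it has;
    only cluster representatives count as surviving records (clustering can
    therefore drop species represented only by near-duplicates of another
    species' sequence).  Clades whose searched-species universe is unknown
    are flagged instead of fractioned.
    """
    known = set(tax.clades())
    for clade in clades:
        if clade not in known:
            raise KeyError(f"clade {clade!r} not present in taxonomy")
    species_with_hit: set[str] = set()
    for rep in assignment.representatives:
        rec = records_by_id[rep]
        if rec.species:
            species_with_hit.add(rec.species)
    rows = []
    for clade in clades:
        searched = tax.universe_count(clade)
        clade_species = set(tax.species_in_clade(clade))
        with_hit = len(species_with_hit & clade_species)
        unknown = searched == 0
        rows.append(
            {
                "clade": clade,
                "species_searched": searched,
                "species_with_hit": with_hit,
                "fraction": (with_hit / searched) if not unknown else float("nan"),
                "universe_unknown": unknown,
            }
        )
    return pd.DataFrame(rows)


def residue_composition(
    annotations: Iterable[AnnotationResult],
    tax: TaxonomyTable,
    clade: str,
    position: int,
) -> dict:
    """Residue counts and percentages at one motif position within a clade.

    Percentages (one decimal) are over determined calls only; ``?`` calls
    are counted separately, matching the convention of not counting partial
    sequences where the residue is missing.
    """
    span_name = next(
        (name for name, span in MOTIF_SPANS.items() if position in span), None
    )
    if span_name is None:
        raise ValueError(f"position {position} is not in any motif span")
    offset = MOTIF_SPANS[span_name].index(position)
    counter: Counter[str] = Counter()
    undetermined = 0
    total = 0
    for a in annotations:
        path = _path_for(a, tax)
        if clade not in path:
            continue
        total += 1
        residue = a.motifs.residues[span_name][offset]
        if residue == "?":
            undetermined += 1
        else:
            counter[residue] += 1
    determined = sum(counter.values())
    percentages = {
        res: round(100.0 * cnt / determined, 1) for res, cnt in counter.items()
    } if determined else {}
    return {
        "clade": clade,
        "position": position,
        "n_records": total,
        "n_determined": determined,
        "n_undetermined": undetermined,
        "counts": dict(counter),
        "percentages": percentages,
        "percentages_defined": determined > 0,
    }


def _path_for(annotation: AnnotationResult, tax: TaxonomyTable) -> tuple[str, ...]:
    rec = annotation.record
    if rec is not None:
        if rec.species in tax:
            return tax.clade_path(rec.species)
        return rec.clade_path
    return ()


def composition_table(
    annotations: Sequence[AnnotationResult],
    tax: TaxonomyTable,
    clades: Sequence[str],
    position: int,
) -> pd.DataFrame:
    """Stacked residue-composition rows, one per clade."""
    rows = []
    for clade in clades:
        comp = residue_composition(annotations, tax, clade, position)
        row = {
            "clade": clade,
            "position": position,
            "n_records": comp["n_records"],
            "n_determined": comp["n_determined"],
            "n_undetermined": comp["n_undetermined"],
        }
        for res, pct in sorted(comp["percentages"].items(), key=lambda kv: -kv[1]):
            row[f"pct_{res}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
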