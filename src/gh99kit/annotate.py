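"""Rule-based functional annotation of GH99 proteins from their motifs.

The rules mirror the structural understanding of the GH99 active site:

* Position 189 selects the -2 subsite sugar: Tyr prefers glucose
  (endomannosidase-like, minimal substrate GlcMan3), Trp prefers mannose
  (endomannanase-like, minimal substrate Man4); other residues (e.g. the
  Leu seen in *Shewanella*) are reported as ``other_residue``.
* The catalytic glutamates are E404 and E407; a mapped non-glutamate at
  either position (e.g. E404Q, or the EWHE->KWHE change seen in falcon
  MANEAL) predicts loss of hydrolase activity.
* The 404-407 string is classified against the known variants
  {EWHE, EWGE, DYGE, KWHE}.  DYGE — the GH71-like motif also found in some
  GH99 proteins — has no activity evidence either way, so its catalytic
  status is reported as undetermined rather than inactive.
* N197H in the -2 loop (D[D/E]HGE instead of D[D/E]NGE, characteristic of
  CMANEAL) is flagged but never overrides the 189/404-407 calls.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import pandas as pd

from .align import build_reference_map
from .motifs import MotifCall, extract_motifs
from .seqio import ProteinRecord

KNOWN_ACTSITE_CLASSES = ("EWHE", "EWGE", "DYGE", "KWHE")

__all__ = ["AnnotationResult", "annotate", "annotate_cohort", "cohort_table"]


@dataclass(frozen=True)
class AnnotationResult:
    record_id: str
    substrate_preference: str  # glc_minus2 | man_minus2 | other_residue | undetermined
    predicted_minimal_substrate: str  # GlcMan3 | Man4 | unknown
    catalytic_status: str  # predicted_active | predicted_inactive | undetermined
    activesite_class: str  # EWHE | EWGE | DYGE | KWHE | other | undetermined
    n197h: str  # present | absent | undetermined
    motifs: MotifCall
    record: ProteinRecord | None = None
    warning: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motifs"] = dict(self.motifs.residues)
        d["record"] = self.record.id if self.record is not None else None
        return d


def _substrate_rules(p189: str) -> tuple[str, str]:
    if p189 == "Y":
        return "glc_minus2", "GlcMan3"
    if p189 == "W":
        return "man_minus2", "Man4"
    if p189 == "?":
        return "undetermined", "unknown"
    return "other_residue", "unknown"


def _actsite_rules(actsite: str) -> tuple[str, str]:
    if "?" in actsite:
        cls = "undetermined"
    elif actsite in KNOWN_ACTSITE_CLASSES:
        cls = actsite
    else:
        cls = "other"
    e404, e407 = actsite[0], actsite[3]
    if cls == "DYGE":
        status = "undetermined"
    elif e404 == "E" and e407 == "E":
        status = "predicted_active"
    elif (e404 not in "E?") or (e407 not in "E?"):
        # a mapped non-glutamate at either catalytic position is decisive
        status = "predicted_inactive"
    else:
        status = "undetermined"
    return status, cls


def annotate_call(call: MotifCall, record: ProteinRecord | None = None,
                  warning: str = "") -> AnnotationResult:
    """Apply the rule table to an already-extracted motif call."""
    preference, substrate = _substrate_rules(call.p189)
    status, cls = _actsite_rules(call.actsite)
    p197 = call.p197
    n197h = "undetermined" if p197 == "?" else ("present" if p197 == "H" else "absent")
    return AnnotationResult(
        record_id=call.record_id,
        substrate_preference=preference,
        predicted_minimal_substrate=substrate,
        catalytic_status=status,
        activesite_class=cls,
        n197h=n197h,
        motifs=call,
        record=record,
        warning=warning,
    )


def annotate(record: ProteinRecord, reference: str | ProteinRecord,
             **align_kwargs) -> AnnotationResult:
    """Annotate one record against the reference.

    An unmappable record (identity below the floor) yields a fully
    undetermined result with a warning, never an exception.
    """
    refmap = build_reference_map(record, reference, **align_kwargs)
    warning = "" if refmap is not None else "unmappable: identity below floor"
    call = extract_motifs(record, refmap)
    return annotate_call(call, record=record, warning=warning)


def annotate_cohort(records: Iterable[ProteinRecord],
                    reference: str | ProteinRecord,
                    **align_kwargs) -> list[AnnotationResult]:
    return [annotate(r, reference, **align_kwargs) for r in records]


def cohort_table(annotations: Iterable[AnnotationResult]) -> pd.DataFrame:
    """Flatten annotations into a cohort TSV-ready table."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "id": a.record_id,
                "p189": a.motifs.p189,
                "loop": a.motifs.loop,
                "hepy": a.motifs.hepy,
                "p323": a.motifs.p323,
                "actsite": a.motifs.actsite,
                "substrate_preference": a.substrate_preference,
                "predicted_minimal_substrate": a.predicted_minimal_substrate,
                "catalytic_status": a.catalytic_status,
                "activesite_class": a.activesite_class,
                "n197h": a.n197h,
                "warning": a.warning,
            }
        )
    return pd.DataFrame(rows)
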