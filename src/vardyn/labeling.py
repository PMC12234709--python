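"""Evidence-based 4-way class labeling of variants.

Per-variant clinical evidence (ClinVar assertion, gnomAD homozygote count and
allele frequency, HGMD disease-mutation flag, clinical-panel call) is turned
into one of four classes: benign (0), damaging (1), unknown (2), ambiguous
(3). For an early-onset recessive disease, a variant observed homozygous in
healthy adults (gnomAD only enrols adults) is inferred benign even when
ClinVar lists it as likely benign or VUS; conflicting evidence is labeled
ambiguous; variants with no evidence at all are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import pandas as pd

CLINVAR_VALUES = ("P", "LP", "VUS", "LB", "B", "conflicting", "absent")
PANEL_VALUES = ("benign", "damaging", "none")


class ClassLabel(IntEnum):
    BENIGN = 0
    DAMAGING = 1
    UNKNOWN = 2
    AMBIGUOUS = 3


@dataclass(frozen=True)
class EvidenceRecord:
    variant: str
    clinvar: str = "absent"
    gnomad_homozygotes: int = 0
    gnomad_af: float | None = None
    hgmd_dm: bool = False
    clinical_panel: str = "none"

    def __post_init__(self) -> None:
        if self.clinvar not in CLINVAR_VALUES:
            raise ValueError(
                f"invalid clinvar value {self.clinvar!r}; accepted: {CLINVAR_VALUES}"
            )
        if self.clinical_panel not in PANEL_VALUES:
            raise ValueError(
                f"invalid clinical_panel {self.clinical_panel!r}; accepted: {PANEL_VALUES}"
            )
        if self.gnomad_homozygotes < 0:
            raise ValueError("gnomad_homozygotes must be >= 0")
        if self.gnomad_homozygotes > 0 and self.gnomad_af is None:
            raise ValueError("gnomad_af must be present when homozygotes > 0")
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError("gnomad_af must be in [0, 1]")


def assign_label(
    evidence: EvidenceRecord,
    disease_model: str = "recessive_early_onset",
    af_threshold: float = 1e-4,
) -> tuple[ClassLabel, str]:
    """Label one variant; returns (label, provenance rule identifier).

    Precedence under the recessive early-onset disease model:

    1. homozygote(s) in gnomAD at an allele frequency compatible with
       recessivity, with ClinVar in {B, LB, VUS, absent} -> benign;
    2. ClinVar P/LP, HGMD DM, or a damaging panel call -> damaging — unless
       the homozygote condition of rule 1 also holds, which forces ambiguous;
    3. ClinVar B/LB or a benign panel call -> benign;
    4. ClinVar conflicting, or benign and damaging evidence both firing
       -> ambiguous;
    5. otherwise -> unknown.
    """
    if disease_model != "recessive_early_onset":
        raise ValueError(f"unsupported disease model {disease_model!r}")
    e = evidence
    hom_ok = (
        e.gnomad_homozygotes >= 1
        and e.gnomad_af is not None
        and e.gnomad_af >= af_threshold
    )
    damaging_ev = e.clinvar in ("P", "LP") or e.hgmd_dm or e.clinical_panel == "damaging"
    benign_ev = e.clinvar in ("B", "LB") or e.clinical_panel == "benign"

    if damaging_ev and hom_ok:
        return ClassLabel.AMBIGUOUS, "damaging_vs_homozygote_conflict"
    if hom_ok and e.clinvar in ("B", "LB", "VUS", "absent"):
        return ClassLabel.BENIGN, "gnomad_homozygote"
    if damaging_ev and benign_ev:
        return ClassLabel.AMBIGUOUS, "benign_vs_damaging_conflict"
    if damaging_ev:
        return ClassLabel.DAMAGING, "clinvar_plp_hgmd_or_panel"
    if benign_ev:
        return ClassLabel.BENIGN, "clinvar_blb_or_panel"
    if e.clinvar == "conflicting":
        return ClassLabel.AMBIGUOUS, "clinvar_conflicting"
    return ClassLabel.UNKNOWN, "no_evidence"


def apply_labels(
    evidence: list[EvidenceRecord] | pd.DataFrame,
    disease_model: str = "recessive_early_onset",
    af_threshold: float = 1e-4,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Label a whole evidence table.

    Returns a DataFrame (variant, label, provenance) and per-class counts
    (counts always sum to the table length). Duplicate variant ids are an
    error.
    """
    if isinstance(evidence, pd.DataFrame):
        evidence = [
            EvidenceRecord(
                variant=row["variant"],
                clinvar=row.get("clinvar", "absent"),
                gnomad_homozygotes=int(row.get("gnomad_homozygotes", 0) or 0),
                gnomad_af=(
                    None
                    if pd.isna(row.get("gnomad_af"))
                    else float(row.get("gnomad_af"))
                ),
                hgmd_dm=bool(row.get("hgmd_dm", False)),
                clinical_panel=row.get("clinical_panel", "none"),
            )
            for _, row in evidence.iterrows()
        ]
    ids = [e.variant for e in evidence]
    if len(set(ids)) != len(ids):
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise ValueError(f"duplicate variant ids: {dupes}")
    rows = []
    for e in evidence:
        label, rule = assign_label(e, disease_model, af_threshold)
        rows.append({"variant": e.variant, "label": int(label), "provenance": rule})
    table = pd.DataFrame(rows, columns=["variant", "label", "provenance"])
    counts = {int(c): 0 for c in ClassLabel}
    for label in table["label"]:
        counts[int(label)] += 1
    return table, counts
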