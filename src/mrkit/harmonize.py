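"""Instrument filtering and allele harmonization between two studies.

Two-sample MR needs every variant's exposure and outcome effects expressed
per copy of the *same* effect allele.  Studies publish effects on whichever
allele their pipeline chose, sometimes on the opposite strand, so aligning
them requires sign flips (swapped alleles), strand complementation
(A<->T, C<->G), and a policy for palindromic variants (A/T or C/G pairs),
whose orientation is ambiguous without frequency information.

Every decision taken for every input variant is recorded in a
:class:`HarmonizationReport`; nothing is dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .datatypes import ExclusionList, HarmonizedDataset, SnpAssociation
from .errors import ValidationError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PalindromicPolicy(str, Enum):
    DROP = "drop"
    INFER_BY_EAF = "infer_by_eaf"
    KEEP = "keep"


@dataclass
class HarmonizationReport:
    """Per-rsid disposition: kept, flipped, or dropped with a reason."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rsid: str, disposition: str, detail: str = "") -> None:
        self.rows.append({"rsid": rsid, "disposition": disposition, "detail": detail})

    @property
    def n_kept(self) -> int:
        return sum(r["disposition"] in ("kept", "flipped") for r in self.rows)

    @property
    def n_dropped(self) -> int:
        return sum(r["disposition"].startswith("dropped") for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rsid", "disposition", "detail"])

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def apply_exclusions(
    records: list[SnpAssociation], exclusions: ExclusionList
) -> tuple[list[SnpAssociation], HarmonizationReport]:
    """Remove screened-out variants (e.g. a pleiotropy look-up hit list).

    Order of the kept records is preserved; every excluded rsid and every
    list entry absent from the records is noted in the report.
    """
    report = HarmonizationReport()
    kept = []
    seen = set()
    for rec in records:
        seen.add(rec.rsid)
        if rec.rsid in exclusions:
            report.add(rec.rsid, "dropped:excluded", exclusions.reason_for(rec.rsid))
        else:
            kept.append(rec)
            report.add(rec.rsid, "kept")
    for rsid in sorted(set(exclusions.rsids) - seen):
        report.add(rsid, "noop:not-in-input", exclusions.reason_for(rsid))
    return kept, report


def _flip(rec: SnpAssociation) -> SnpAssociation:
    """Re-express an association on the other allele: swap labels, negate beta."""
    return SnpAssociation(
        rsid=rec.rsid,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        se=rec.se,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
        pvalue=rec.pvalue,
    )


def _match_orientation(exp: SnpAssociation, out: SnpAssociation) -> str | None:
    """How do the outcome alleles relate to the exposure's?

    Returns 'same', 'swapped', or None (irreconcilable).  Strand
    complementation is tried after direct label matching.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "same"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swapped"
    cea, coa = _COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]
    if (cea, coa) == (ea, oa):
        return "same"
    if (cea, coa) == (oa, ea):
        return "swapped"
    return None


def harmonize(
    exposure: list[SnpAssociation],
    outcome: list[SnpAssociation],
    palindromic_policy: PalindromicPolicy | str = PalindromicPolicy.INFER_BY_EAF,
    eaf_threshold: float = 0.42,
    trait_name: str = "",
    exposure_scale: str = "",
) -> tuple[HarmonizedDataset, HarmonizationReport]:
    """Align outcome effects to each exposure variant's effect allele.

    Variants absent from the outcome study are dropped and reported
    ("not found in outcome").  Palindromic variants are handled per policy:
    ``drop`` removes them; ``infer_by_eaf`` orients by allele frequency and
    drops those whose frequency falls in the ambiguous window
    [eaf_threshold, 1 - eaf_threshold]; ``keep`` assumes both studies report
    on the same strand.
    """
    policy = PalindromicPolicy(palindromic_policy)
    if not (0.0 < eaf_threshold < 0.5):
        raise ValidationError("eaf_threshold must lie in (0, 0.5)")
    if not exposure or not outcome:
        raise ValidationError("both exposure and outcome lists must be non-empty")

    out_by_rsid: dict[str, SnpAssociation] = {}
    for rec in outcome:
        if rec.rsid in out_by_rsid:
            raise ValidationError(f"duplicate rsid in outcome table: {rec.rsid}")
        out_by_rsid[rec.rsid] = rec

    report = HarmonizationReport()
    rows: list[tuple[SnpAssociation, SnpAssociation]] = []
    seen = set()
    for exp in exposure:
        if exp.rsid in seen:
            raise ValidationError(f"duplicate rsid in exposure table: {exp.rsid}")
        seen.add(exp.rsid)
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            report.add(exp.rsid, "dropped:not-found", "not found in outcome")
            continue

        if exp.is_palindromic:
            if not out.is_palindromic or set(out.effect_allele + out.other_allele) != set(
                exp.effect_allele + exp.other_allele
            ):
                report.add(exp.rsid, "dropped:allele-mismatch", "allele mismatch")
                continue
            if policy is PalindromicPolicy.DROP:
                report.add(exp.rsid, "dropped:palindromic", "palindromic SNP")
                continue
            if policy is PalindromicPolicy.INFER_BY_EAF:
                if exp.eaf is None or out.eaf is None:
                    report.add(
                        exp.rsid, "dropped:palindromic-no-eaf",
                        "palindromic, allele frequency unavailable",
                    )
                    continue
                ambiguous = any(
                    eaf_threshold <= f <= 1.0 - eaf_threshold for f in (exp.eaf, out.eaf)
                )
                if ambiguous:
                    report.add(
                        exp.rsid, "dropped:palindromic-ambiguous",
                        f"palindromic, eaf in ambiguous window "
                        f"[{eaf_threshold}, {1 - eaf_threshold:g}]",
                    )
                    continue
                # frequencies on the same side of 0.5 => same allele; else flip
                if (exp.eaf < 0.5) == (out.eaf < 0.5):
                    rows.append((exp, out))
                    report.add(exp.rsid, "kept", "palindromic, oriented by eaf")
                else:
                    rows.append((exp, _flip(out)))
                    report.add(exp.rsid, "flipped", "palindromic, flipped by eaf")
                continue
            # KEEP: same-strand assumption, match by labels below
        orientation = _match_orientation(exp, out)
        if orientation is None:
            report.add(exp.rsid, "dropped:allele-mismatch", "allele mismatch")
        elif orientation == "same":
            rows.append((exp, out))
            report.add(exp.rsid, "kept")
        else:
            rows.append((exp, _flip(out)))
            report.add(exp.rsid, "flipped", "outcome alleles swapped")

    if not rows:
        raise ValidationError(
            f"harmonization retained no variants for trait {trait_name!r}"
        )

    data = HarmonizedDataset(
        snp_ids=[e.rsid for e, _ in rows],
        beta_exposure=[e.beta for e, _ in rows],
        se_exposure=[e.se for e, _ in rows],
        beta_outcome=[o.beta for _, o in rows],
        se_outcome=[o.se for _, o in rows],
        trait_name=trait_name,
        exposure_scale=exposure_scale,
    )
    return data, report


def orient_positive(data: HarmonizedDataset) -> HarmonizedDataset:
    """Re-express every instrument so its exposure effect is positive.

    Required before an Egger regression, whose intercept is only meaningful
    once instrument coding is aligned with the exposure-increasing allele.
    Per-SNP ratio estimates are unchanged (both betas flip together).
    """
    zero = np.flatnonzero(data.beta_exposure == 0)
    if zero.size:
        raise ValidationError(
            f"beta_exposure is exactly 0 for {[data.snp_ids[i] for i in zero]}"
        )
    sign = np.sign(data.beta_exposure)
    return HarmonizedDataset(
        snp_ids=data.snp_ids,
        beta_exposure=data.beta_exposure * sign,
        se_exposure=data.se_exposure,
        beta_outcome=data.beta_outcome * sign,
        se_outcome=data.se_outcome,
        trait_name=data.trait_name,
        exposure_scale=data.exposure_scale,
    )
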