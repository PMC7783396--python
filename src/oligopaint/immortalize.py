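"""Immortalized probe constructs: primer-flanked oligos, PCR audit, and
Sau3AI digestion prediction.

A synthesized library becomes renewable ("immortal") by flanking each
probe with universal primer-annealing sites: a 20-nt 5' site complementary
to a labeled forward primer (T7 by default) and a 20-nt 3' site carrying a
Sau3AI recognition site (GATC). After PCR with one labeled primer, Sau3AI
digestion removes the unlabeled 3' tail, leaving the labeled 5'-site+insert
as the probe. Sau3AI is modeled as cutting immediately 5' of each GATC on
the top strand; the 4-nt 5' overhang it leaves is bookkeeping metadata, as
only product lengths matter for probe prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .core import Oligo, revcomp

SAU3AI_SITE = "GATC"

#: 3' primer-annealing site as published for this probe system
DEFAULT_REV_SITE = "GATCTCTGCATCTAGTAATG"

#: canonical T7 promoter primer (20-mer); the 5' site is its complement target
DEFAULT_T7_PRIMER = "TAATACGACTCACTATAGGG"

#: published unlabeled reverse primer
DEFAULT_REV_PRIMER = "CTAGAAGTTACTGAGAGATC"


@dataclass
class ImmortalConstruct:
    fwd_site: str
    insert: str
    rev_site: str
    full_sequence: str
    warnings: List[str] = field(default_factory=list)
    oligo_id: Optional[str] = None


@dataclass
class DigestionResult:
    fragments: List[Tuple[str, bool]]  # (sequence, labeled)
    labeled_product_length: int


@dataclass
class PrimerAuditReport:
    fwd_provided: bool
    rev_provided: bool
    fwd_agreement: float  # fraction of positions where fwd primer == fwd site
    rev_agreement: float  # fraction where revcomp(rev primer) == rev site
    fwd_mismatch_positions: List[int]
    rev_mismatch_positions: List[int]
    flags: List[str]


def build_construct(
    oligo: Oligo,
    fwd_site: str = DEFAULT_T7_PRIMER,
    rev_site: str = DEFAULT_REV_SITE,
) -> ImmortalConstruct:
    """Assemble 5'site + insert + 3'site and check digestibility.

    The reverse site must contain the Sau3AI recognition sequence GATC,
    otherwise the 3' tail could never be removed. A GATC inside the forward
    site or the insert is legal but predicts a truncated labeled product,
    so it raises a warning rather than an error.
    """
    if len(fwd_site) != 20 or len(rev_site) != 20:
        raise ValueError("primer-annealing sites must be 20 nt")
    if SAU3AI_SITE not in rev_site:
        raise ValueError(
            "rev_site lacks the Sau3AI site GATC: digestion impossible"
        )
    warnings: List[str] = []
    if SAU3AI_SITE in fwd_site:
        warnings.append("GATC inside fwd_site: labeled product will be truncated")
    if SAU3AI_SITE in oligo.sequence:
        warnings.append("GATC inside insert: labeled product will be truncated")
    return ImmortalConstruct(
        fwd_site=fwd_site,
        insert=oligo.sequence,
        rev_site=rev_site,
        full_sequence=fwd_site + oligo.sequence + rev_site,
        warnings=warnings,
        oligo_id=oligo.oligo_id,
    )


def digest_sau3ai(
    construct: ImmortalConstruct, labeled_end: str = "five_prime"
) -> DigestionResult:
    """Cut 5' of every GATC on the top strand; flag the labeled fragment.

    With a labeled forward primer the fragment containing position 0 carries
    the label. Fragment lengths always sum to the construct length.
    """
    if labeled_end != "five_prime":
        raise ValueError("only 5'-labeled amplification is modeled")
    seq = construct.full_sequence
    cuts: List[int] = []
    pos = seq.find(SAU3AI_SITE)
    while pos != -1:
        if pos > 0:  # a site at position 0 yields no fragment boundary
            cuts.append(pos)
        pos = seq.find(SAU3AI_SITE, pos + 1)
    bounds = [0] + cuts + [len(seq)]
    fragments = [
        (seq[a:b], a == 0) for a, b in zip(bounds, bounds[1:]) if b > a
    ]
    labeled_len = next(len(s) for s, lab in fragments if lab)
    return DigestionResult(fragments=fragments, labeled_product_length=labeled_len)


def primer_audit(
    fwd_primer: str,
    rev_primer: str,
    construct: ImmortalConstruct,
) -> PrimerAuditReport:
    """Check the primer pair against the construct's annealing sites.

    The forward primer should equal the 5' site in sense orientation; the
    reverse complement of the reverse primer should equal the 3' site.
    Disagreements are flagged per position, never raised: published primer
    pairs are sometimes imperfectly complementary to their printed sites and
    the toolkit reports rather than silently corrects this.
    """

    def _compare(a: str, b: str) -> Tuple[float, List[int]]:
        n = min(len(a), len(b))
        mism = [i for i in range(n) if a[i] != b[i]]
        mism += list(range(n, max(len(a), len(b))))
        denom = max(len(a), len(b))
        return (denom - len(mism)) / denom if denom else 0.0, mism

    flags: List[str] = []
    fwd_provided = bool(fwd_primer)
    rev_provided = bool(rev_primer)
    if fwd_provided:
        fwd_agree, fwd_mm = _compare(fwd_primer, construct.fwd_site)
        if fwd_mm:
            flags.append(
                f"forward primer mismatches fwd_site at {len(fwd_mm)} position(s)"
            )
    else:
        fwd_agree, fwd_mm = 0.0, []
        flags.append("forward primer not provided")
    if rev_provided:
        rev_agree, rev_mm = _compare(revcomp(rev_primer), construct.rev_site)
        if rev_mm:
            flags.append(
                "reverse primer is not the exact reverse complement of "
                f"rev_site ({len(rev_mm)} position(s) differ)"
            )
    else:
        rev_agree, rev_mm = 0.0, []
        flags.append("reverse primer not provided")
    return PrimerAuditReport(
        fwd_provided=fwd_provided,
        rev_provided=rev_provided,
        fwd_agreement=fwd_agree,
        rev_agreement=rev_agree,
        fwd_mismatch_positions=fwd_mm,
        rev_mismatch_positions=rev_mm,
        flags=flags,
    )


#: touchdown thermal profile used for library amplification, recorded as
#: protocol metadata only (thermodynamics are not simulated)
PCR_PROTOCOL_METADATA = {
    "denature_c": 98,
    "anneal_start_c": 59,
    "anneal_end_c": 53,
    "touchdown_step_c": 2,
    "extension_c": 72,
}
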