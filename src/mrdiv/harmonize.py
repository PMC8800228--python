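"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs the exposure and outcome effects of each variant
expressed per copy of the *same* effect allele.  Outcome records whose
alleles are swapped relative to the exposure have their beta negated;
records reported on the opposite strand are complemented first.
Palindromic variants (A/T or C/G) cannot be oriented from alleles alone,
so they are handled by policy: drop them, keep them assuming same-strand
reporting, or infer orientation from allele frequencies (dropping
frequencies too close to 0.5 to call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .summary_io import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: exposure effects below this magnitude make the Wald ratio numerically
#: unstable (its variance divides by beta_x**2) and are dropped
WEAK_ZERO = 1e-12

PALINDROME_POLICIES = ("drop", "keep", "eaf_infer")


@dataclass
class HarmonizedVariant:
    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    flipped: bool = False
    ambiguous: bool = False
    eaf_x: float | None = None


@dataclass
class HarmonizedPanel:
    """Exposure/outcome effects aligned to a shared effect allele per variant."""

    exposure_label: str
    outcome_label: str
    variants: list[HarmonizedVariant] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def subset(self, rsids) -> "HarmonizedPanel":
        keep = set(rsids)
        return HarmonizedPanel(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            variants=[v for v in self.variants if v.rsid in keep],
            dropped=list(self.dropped),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [v.rsid for v in self.variants],
                "beta_x": [v.beta_x for v in self.variants],
                "se_x": [v.se_x for v in self.variants],
                "beta_y": [v.beta_y for v in self.variants],
                "se_y": [v.se_y for v in self.variants],
                "flipped": [v.flipped for v in self.variants],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_panel(
    path: str | Path, exposure_label: str = "exposure", outcome_label: str = "outcome"
) -> HarmonizedPanel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    panel = HarmonizedPanel(exposure_label=exposure_label, outcome_label=outcome_label)
    for row in df.itertuples(index=False):
        panel.variants.append(
            HarmonizedVariant(
                rsid=row.rsid,
                beta_x=row.beta_x,
                se_x=row.se_x,
                beta_y=row.beta_y,
                se_y=row.se_y,
                flipped=bool(getattr(row, "flipped", False)),
            )
        )
    return panel


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize_pair(
    exposure_rec: VariantAssociation,
    outcome_rec: VariantAssociation,
    palindrome_policy: str = "eaf_infer",
    eaf_window: float = 0.08,
) -> HarmonizedVariant | str:
    """Orient one outcome record onto the exposure's effect allele.

    Returns a HarmonizedVariant, or a drop-reason string when the pair
    cannot be reconciled.  ``eaf_window`` is the half-width around 0.5
    inside which an allele frequency is too uninformative to orient a
    palindromic variant (default 0.08, i.e. drop EAF in [0.42, 0.58]).
    """
    if exposure_rec.rsid != outcome_rec.rsid:
        raise ValueError("rsid mismatch between exposure and outcome records")
    if palindrome_policy not in PALINDROME_POLICIES:
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")

    e1, o1 = exposure_rec.effect_allele, exposure_rec.other_allele
    e2, o2 = outcome_rec.effect_allele, outcome_rec.other_allele
    if abs(exposure_rec.beta) < WEAK_ZERO:
        return "weak-zero"

    def build(beta_y: float, flipped: bool, ambiguous: bool = False) -> HarmonizedVariant:
        return HarmonizedVariant(
            rsid=exposure_rec.rsid,
            beta_x=exposure_rec.beta,
            se_x=exposure_rec.se,
            beta_y=beta_y,
            se_y=outcome_rec.se,
            flipped=flipped,
            ambiguous=ambiguous,
            eaf_x=exposure_rec.eaf,
        )

    if not is_palindromic(e1, o1):
        if (e2, o2) == (e1, o1):
            return build(outcome_rec.beta, flipped=False)
        if (e2, o2) == (o1, e1):
            return build(-outcome_rec.beta, flipped=True)
        ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
        if (ce2, co2) == (e1, o1):
            return build(outcome_rec.beta, flipped=False)
        if (ce2, co2) == (o1, e1):
            return build(-outcome_rec.beta, flipped=True)
        return "allele-mismatch"

    # palindromic exposure: outcome alleles must be the same base pair,
    # but strand cannot be resolved from the letters
    if {e2, o2} != {e1, o1}:
        return "allele-mismatch"
    letter_flip = e2 != e1  # aligned on reported letters only
    if palindrome_policy == "drop":
        return "palindromic"
    if palindrome_policy == "keep":
        beta_y = -outcome_rec.beta if letter_flip else outcome_rec.beta
        return build(beta_y, flipped=letter_flip, ambiguous=True)

    # eaf_infer: compare which-side-of-0.5 of the two frequencies
    eaf_x, eaf_y = exposure_rec.eaf, outcome_rec.eaf
    if eaf_x is None or eaf_y is None:
        return "palindromic-ambiguous"
    if letter_flip:
        eaf_y = 1.0 - eaf_y
    lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
    if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
        return "palindromic-ambiguous"
    if (eaf_x < 0.5) == (eaf_y < 0.5):
        beta_y = -outcome_rec.beta if letter_flip else outcome_rec.beta
        return build(beta_y, flipped=letter_flip)
    # frequencies disagree: the outcome is on the opposite strand, so the
    # reported effect allele matches the exposure's other allele
    beta_y = outcome_rec.beta if letter_flip else -outcome_rec.beta
    return build(beta_y, flipped=not letter_flip)


def harmonize_panel(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    rsids: list[str] | None = None,
    palindrome_policy: str = "eaf_infer",
    eaf_window: float = 0.08,
) -> HarmonizedPanel:
    """Harmonize every requested variant; drops are data, not errors.

    ``rsids`` defaults to the exposure variants present in the outcome;
    variants absent from the outcome are dropped with a logged count.
    """
    if rsids is None:
        rsids = [r for r in exposure.records if r in outcome.records]
        n_missing = len(exposure.records) - len(rsids)
        if n_missing:
            logger.info(
                "%s: %d exposure variants absent from outcome %s",
                exposure.label,
                n_missing,
                outcome.label,
            )
    panel = HarmonizedPanel(exposure_label=exposure.label, outcome_label=outcome.label)
    for rsid in rsids:
        if rsid not in exposure.records or rsid not in outcome.records:
            panel.dropped.append((rsid, "missing"))
            continue
        result = harmonize_pair(
            exposure.records[rsid],
            outcome.records[rsid],
            palindrome_policy=palindrome_policy,
            eaf_window=eaf_window,
        )
        if isinstance(result, str):
            panel.dropped.append((rsid, result))
        else:
            panel.variants.append(result)
    if not panel.variants:
        raise ValueError(
            f"harmonization of {exposure.label} vs {outcome.label} left no instruments"
        )
    return panel
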