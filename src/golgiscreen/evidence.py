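"""Literature knockdown-phenotype scoring (score component 1).

The rubric exploits the fact that each cell-line pair couples an expression
contrast to a Golgi phenotype contrast. If a gene is lower-expressed in,
say, the disorganized line, then knocking it down should — if the gene
drives the phenotype — reproduce disorganization. Concordance between the
reported knockdown phenotype and the phenotype of the low-expression line
scores 2; reported-but-discordant data scores 1; no knockdown data scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from golgiscreen.screen import EQUAL, HIGHER_IN_DISORGANIZED, HIGHER_IN_ORGANIZED, CellLinePair

DISORGANIZED = "disorganized"
ORGANIZED_OR_CONDENSED = "organized_or_condensed"
NONE_REPORTED = "none_reported"

KNOCKDOWN_PHENOTYPES = (DISORGANIZED, ORGANIZED_OR_CONDENSED, NONE_REPORTED)


@dataclass(frozen=True)
class EvidenceRecord:
    """Curated literature record for one gene's knockdown effect on the Golgi."""

    gene: str
    knockdown_phenotype: str
    golgi_involvement: bool

    def __post_init__(self) -> None:
        if self.knockdown_phenotype not in KNOCKDOWN_PHENOTYPES:
            raise ValueError(f"unknown knockdown phenotype {self.knockdown_phenotype!r}")


@dataclass(frozen=True)
class PhenotypeContext:
    """The pair and the gene's DEG direction, fixing which phenotype concordance predicts."""

    pair: CellLinePair
    direction: str


@dataclass(frozen=True)
class LiteratureScore:
    gene: str
    score1: int
    rationale: str


def predicted_low_expression_phenotype(ctx: PhenotypeContext) -> str:
    """Golgi phenotype of the cell line where the gene is lower-expressed.

    This is the phenotype a knockdown should reproduce under concordance:
    a gene higher in the organized line is low in the disorganized line, so
    the concordant knockdown phenotype is ``disorganized`` (and vice versa).
    """
    if ctx.direction == HIGHER_IN_ORGANIZED:
        return DISORGANIZED
    if ctx.direction == HIGHER_IN_DISORGANIZED:
        return ORGANIZED_OR_CONDENSED
    if ctx.direction == EQUAL:
        raise ValueError("direction 'equal' has no low-expression line")
    raise ValueError(f"unknown direction {ctx.direction!r}")


def literature_score(ev: EvidenceRecord, ctx: PhenotypeContext) -> LiteratureScore:
    """Apply the 0/1/2 rubric to one evidence record.

    2 — knockdown phenotype matches the phenotype predicted from the
    expression pattern (concordant); 1 — knockdown data exists but is
    discordant; 0 — no knockdown data reported.
    """
    if ev.knockdown_phenotype == NONE_REPORTED:
        return LiteratureScore(gene=ev.gene, score1=0, rationale="no_data")
    if ev.knockdown_phenotype == predicted_low_expression_phenotype(ctx):
        return LiteratureScore(gene=ev.gene, score1=2, rationale="concordant")
    rationale = "involved_discordant" if ev.golgi_involvement else "discordant"
    return LiteratureScore(gene=ev.gene, score1=1, rationale=rationale)
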