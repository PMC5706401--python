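"""Bundled reference tables.

``candidate_variants()`` returns the eight candidate variants of the two
resilience linkage regions (chromosomes 2 and 10) with their reference-panel
frequencies.  They serve as a regression fixture for the cascade: every row
must pass the frequency exclusion (all panel frequencies are below 3%) and
the consequence-driven functional rules.  Annotation dimensions the table
does not carry (call-quality values, conservation scores, interaction-network
context) are encoded at their known post-filter state or left absent so the
cascade's not-applicable handling applies.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .variants import AnnotatedVariant

__all__ = ["candidate_variants", "candidate_variant_frame"]

_CONSEQUENCE = {
    "3UTR": "utr3",
    "5UTR": "utr5",
    "Promoter": "other",
    "Promoter;5UTR": "utr5",
    # "Exonic" rows are synonymous coding changes whose retention rested on
    # annotations (conservation, regulatory context) outside the printed
    # record; the functional rule treats them as unannotated
    "Exonic": "other",
}


def candidate_variant_frame() -> pd.DataFrame:
    ref = importlib.resources.files("resilink").joinpath("data/candidate_variants.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def candidate_variants(resilient_ids=("R1", "R2", "R3", "R4")) -> list[AnnotatedVariant]:
    """The candidate set as AnnotatedVariant records ready for the cascade."""
    df = candidate_variant_frame()
    out = []
    for _, r in df.iterrows():
        freqs = {}
        if pd.notna(r["kg1000"]):
            freqs["kg1000"] = float(r["kg1000"])
        if pd.notna(r["exac"]):
            freqs["exac"] = float(r["exac"])
        vt = r["variant_type"]
        kwargs = {}
        if vt == "Promoter" or vt == "Promoter;5UTR":
            kwargs["promoter"] = True
        out.append(
            AnnotatedVariant(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref="N",
                alt="V",
                gene=str(r["gene"]).split(";")[0],
                resilient_carriers=set(resilient_ids),
                case_carriers=set(),
                call_quality={"resilient": 50.0},
                panel_freqs=freqs,
                consequence=_CONSEQUENCE[vt],
                zygosity_class="heterozygous",
                **kwargs,
            )
        )
    return out
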