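"""Published reference records used as worked-example inputs.

The 13 salt-responsive differentially expressed lncRNAs reported for the
contrasting rice genotypes FL478 (salt tolerant) and IR29 (salt sensitive),
with their genomic coordinates, lengths, log2 fold changes (salt vs control)
and Cuffcompare class codes, plus the published per-category lncRNA tallies
for FL478.  Coordinates reproduce the published Start/End columns, whose
difference equals the published Length under half-open arithmetic.

Every record in ``RICE_SALT_DE_LNCRNAS`` passed the study's significance cut
(q <= 0.05); q-values were not tabulated per transcript, so ``qvalue`` holds
the value quoted in the accompanying text where one exists and a nominal
passing value (0.01) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import GenomicInterval

__all__ = ["DELncRNARecord", "RICE_SALT_DE_LNCRNAS", "FL478_CLASS_COUNTS", "FL478_TOTAL_LNCRNAS"]


@dataclass(frozen=True)
class DELncRNARecord:
    genotype: str  # "FL478" (tolerant) or "IR29" (sensitive)
    seq_id: str
    name: str
    chrom: str
    start: int
    end: int
    length: int
    log2fc: float
    class_code: str
    qvalue: float = 0.01

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, ".")


RICE_SALT_DE_LNCRNAS: list[DELncRNARecord] = [
    # FL478 (tolerant): 2 up, 2 down
    DELncRNARecord("FL478", "TCONS_00038460", "lncRNA.1*", "2", 9_106_571, 9_107_483, 912, -1.84777, "o"),
    DELncRNARecord("FL478", "TCONS_00088492", "lncRNA.2-FL", "6", 21_764_438, 21_765_266, 828, 1.33505, "o"),
    DELncRNARecord("FL478", "TCONS_00110513", "lncRNA.3-FL", "9", 19_868_030, 19_868_740, 710, -1.84449, "o"),
    DELncRNARecord("FL478", "TCONS_00069370", "lncRNA.4*", "4", 25_515_690, 25_516_406, 716, 1.3109, "o"),
    # IR29 (sensitive): 6 up, 3 down
    DELncRNARecord("IR29", "TCONS_00038953", "lncRNA.1*", "2", 9_106_569, 9_107_483, 914, -2.84421, "o", 0.0012),
    DELncRNARecord("IR29", "TCONS_00109665", "lncRNA.2-IR", "8", 13_484_779, 13_485_797, 1018, 2.43485, "u"),
    DELncRNARecord("IR29", "TCONS_00014111", "lncRNA.3-IR", "1", 23_750_606, 23_751_636, 1030, 1.77214, "o"),
    DELncRNARecord("IR29", "TCONS_00070354", "lncRNA.4*", "4", 25_515_690, 25_516_422, 732, 1.20362, "o"),
    DELncRNARecord("IR29", "TCONS_00015930", "lncRNA.5-IR", "10", 8_069_944, 8_070_766, 822, -19.3908, "o"),
    DELncRNARecord("IR29", "TCONS_00003216", "lncRNA.6-IR", "1", 24_908_220, 24_909_529, 1309, -1.70111, "o"),
    DELncRNARecord("IR29", "TCONS_00073667", "lncRNA.7-IR", "4", 24_983_145, 24_983_890, 745, 2.11511, "u"),
    DELncRNARecord("IR29", "TCONS_00028639", "lncRNA.8-IR", "11", 2_932_659, 2_933_342, 683, 1.21378, "o"),
    DELncRNARecord("IR29", "TCONS_00076916", "lncRNA.9-IR", "5", 26_093_812, 26_095_238, 1426, 1.81551, "o"),
]

# Published per-category lncRNA tally for FL478 (sense / antisense / lincRNA /
# intronic) and the published total they sum to.
FL478_CLASS_COUNTS: dict[str, int] = {
    "sense": 93,
    "antisense": 8,
    "lincRNA": 27,
    "intronic": 4,
}
FL478_TOTAL_LNCRNAS = 132


def records_for(genotype: str) -> list[DELncRNARecord]:
    return [r for r in RICE_SALT_DE_LNCRNAS if r.genotype == genotype]
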