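"""Small shared helpers for the test suite."""

from gdprisk.datatypes import VariantRecord


def simple_variants(m: int, chrom: str = "1", spacing: int = 100):
    return [
        VariantRecord(chrom=chrom, pos=1 + j * spacing, vid=f"t{j}", ref="A", alt="G")
        for j in range(m)
    ]
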