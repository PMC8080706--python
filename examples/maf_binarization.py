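"""Binarize a MAF file into the samples x genes mutation matrix.

Writes a tiny MAF (the cBioPortal tab-separated dialect) to a temporary
file, converts it with the default nonsilent-coding class filter, and
prints the resulting binary matrix.
"""

import tempfile
from pathlib import Path

from ragnmf import DEFAULT_QUALIFYING_CLASSES, maf_to_matrix

records = [
    ("TP53", "TCGA-01", "Missense_Mutation"),
    ("TP53", "TCGA-02", "Nonsense_Mutation"),
    ("BRCA1", "TCGA-01", "Frame_Shift_Del"),
    ("BRCA1", "TCGA-03", "Silent"),        # does not qualify
    ("KRAS", "TCGA-02", "3'UTR"),          # does not qualify
]

with tempfile.TemporaryDirectory() as tmp:
    maf = Path(tmp) / "example.maf"
    maf.write_text(
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
        + "".join(f"{g}\t{s}\t{c}\n" for g, s, c in records)
    )
    matrix = maf_to_matrix(maf)

print(f"qualifying classes ({len(DEFAULT_QUALIFYING_CLASSES)}): nonsilent coding mutations")
print(f"matrix: {matrix.n_samples} samples x {matrix.n_genes} genes\n")
print(matrix.to_frame())
print("\nSilent and UTR records contribute no entry; TCGA-03 and KRAS carry")
print("no qualifying mutation and so do not appear at all.")
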