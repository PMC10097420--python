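"""Call validation status from the packaged pyrosequencing survey.

Loads the 49-gene allele-specific pyrosequencing summary (corrected
reciprocal-mean paternal percentages over 13 tissues) and applies the
calling rules: >55% paternal, <45% maternal, [45,55] biallelic; genes whose
only out-of-window tissue is the placenta are Placental; genes with no
callable tissue are Low expression.
"""

import warnings
from collections import Counter

from poebias.datasets import PLACENTA_TISSUES, load_validation_summary, summary_tissue_means
from poebias.validation import call_gene

df = load_validation_summary()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    calls = {
        row.gene_id: call_gene(row.gene_id, summary_tissue_means(row), PLACENTA_TISSUES)
        for _, row in df.iterrows()
    }

for cls in ("1", "2", "3", "K"):
    genes = df[df.gene_class == cls].gene_id
    counts = Counter(calls[g].category for g in genes)
    print(f"class {cls}: {dict(sorted(counts.items()))}")

print("\nexamples:")
for g in ("Nhlrc1", "Stx6", "Vat1", "Peg3"):
    print(f"  {g:8s} -> {calls[g].category}")
# Most class-1/2 candidates fail to validate (biallelic or unexpressed);
# candidates near known clusters (class 3) validate far more often.
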