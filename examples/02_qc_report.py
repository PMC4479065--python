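"""Quality control on a small constructed SNP set with known defects.

The demonstration set has 30 individuals and 8 SNPs: two below the MAF
threshold (one of them also under-called), one all-heterozygous SNP
(failing both the Hardy-Weinberg test and the heterozygosity-excess
screen), one X-chromosome SNP and four clean autosomal SNPs.
"""

import breedld as bl
from breedld.validation import qc_demo_config, qc_demo_dataset

geno, markers = qc_demo_dataset()
filtered, markers_kept, report = bl.apply_qc(geno, markers, qc_demo_config())

print(report.to_frame().to_string(index=False))
print()
print("failures by criterion:")
for criterion, names in report.failed_by_criterion.items():
    print(f"  {criterion:>11}: {sorted(map(str, names))}")
print(f"survivors: {[str(n) for n in markers_kept.name]}")

# The per-criterion counts sum to 5 but only 3 distinct SNPs fail: snp3
# is short of both the MAF and call-rate thresholds and snp4 trips both
# the HWE test and the heterozygosity excess.  8 input - 1 non-autosomal
# - 3 failing = 4 SNPs remain for the LD analyses.
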