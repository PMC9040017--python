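"""Validating peak calls against a reference open-chromatin set.

A called peak is validated by >= 1 bp of overlap with the reference
(e.g. DNase I hypersensitive sites); unvalidated peaks give an FDR-like
error rate and missed reference elements an FNR-like rate.  Shown on a
synthetic library (called vs planted peaks) and on published
GM12878 validation counts (112,848 PE-asSE peaks of which 3,575 lacked
DHS support).
"""
from atacqc import (calls_to_peakset, deduplicate, filter_pairs, merge_peaks,
                    naive_call_peaks, useful_ends, validate_peaks, Interval)
from atacqc.synthetic import SimulationConfig, simulate_genome, simulate_pairs

cfg = SimulationConfig(seed=4, n_pairs=20_000)
sizes, planted, _ = simulate_genome(cfg)
pairs, _ = simulate_pairs(cfg, sizes, planted)
unique, _ = deduplicate(filter_pairs(pairs)[0])
ends = useful_ends(unique, "pseudoSE", sizes)
called = calls_to_peakset(naive_call_peaks(ends, sizes))

res = validate_peaks(called, planted)
print(f"called peaks: {res.n_peaks}; planted reference: {res.n_reference}")
print(f"unvalidated (FDR-like): {res.n_unvalidated} -> {100*res.fdr_like:.2f}%")
print(f"missed reference (FNR-like): {res.n_missed} -> {100*res.fnr_like:.2f}%")

# Arithmetic on published GM12878 counts: 3,575 of 112,848 peaks
# without DHS support -> 3.17% potential type-I error.
n_total, n_off = 112_848, 3_575
peaks = merge_peaks([Interval("chr1", 100 * i, 100 * i + 50)
                     for i in range(n_total)])
reference = merge_peaks([Interval("chr1", 100 * i, 100 * i + 50)
                         for i in range(n_total - n_off)])
res = validate_peaks(peaks, reference)
print(f"published-count check: {res.n_unvalidated}/{res.n_peaks} "
      f"-> {100*res.fdr_like:.2f}% (expected 3.17%)")
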