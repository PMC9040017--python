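"""Full QC run on a simulated ATAC-seq library.

Simulates a 1.8 Mb genome with 60 planted open-chromatin peaks and
20,000 read pairs (30% inside peaks, 10% duplicates, 5% chrM), then
computes the key QC metrics with the bundled Poisson-tile peak caller.
High RUPr/ProEn mean strong signal enrichment; background reflects
noise outside peaks; SubEn is shrunk toward 1 by the pseudo-counts at
this small depth.
"""
from atacqc import (background_metric, promoter_enrichment,
                    promoter_peak_fraction, promoters_from_tss, rupr,
                    subsampling_enrichment, useful_ends, deduplicate,
                    filter_pairs, naive_call_peaks, calls_to_peakset)
from atacqc.synthetic import SimulationConfig, simulate_genome, simulate_pairs

cfg = SimulationConfig(seed=1, n_pairs=20_000)
sizes, planted, tss = simulate_genome(cfg)
pairs, truth = simulate_pairs(cfg, sizes, planted)

kept, n_lowq = filter_pairs(pairs)
unique, dup_rate = deduplicate(kept)
ends = useful_ends(unique, "pseudoSE", sizes)
caller = lambda e: calls_to_peakset(naive_call_peaks(e, sizes))
peaks = caller(ends)
promoters = promoters_from_tss(tss, sizes)

print(f"pairs={len(pairs)} low_mapq={n_lowq} unique={len(unique)} "
      f"duplication_rate={dup_rate:.3f}")
print(f"useful ends (PE-asSE): {ends.e_total}; called peaks: {len(peaks)} "
      f"covering {peaks.total_length} bp (planted: {planted.total_length} bp)")
print(f"RUPr   = {rupr(ends, peaks):.3f}   (planted in-peak fraction "
      f"{truth.realized_in_peak_fraction:.3f})")
bg = background_metric(ends, peaks, sizes, seed=2)
print(f"BG     = {bg.background:.3f}   ({bg.n_high}/{bg.n_regions} regions over "
      f"RPKM {bg.rpkm_threshold}; large at this shallow depth)")
print(f"ProEn  = {promoter_enrichment(ends, peaks, promoters, sizes):.2f}   "
      "(promoter-peak end density over genome average)")
sub = subsampling_enrichment(ends, sizes, caller, seed=3)
print(f"SubEn  = {sub.suben:.3f}   (10M pseudo-counts shrink it toward 1 "
      f"at {sub.e_sampled} sampled ends)")
print(f"promoter peak fraction = {promoter_peak_fraction(peaks, promoters):.2f}")
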