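"""LOESS GC-bias correction: inject a bias, watch the correction remove it.

Read counts per bin depend on bin GC content through library preparation
bias; left uncorrected this masquerades as copy-number signal. This script
simulates a 10 Mb genome twice — once with a 30% sin-bump GC bias centred at
GC 0.45, once without — corrects both with the LOESS procedure
(corrected = raw * median / fit(GC)) and prints the linear count-vs-GC
slopes before and after. The biased slope should collapse; the unbiased run
should be essentially untouched.
"""

from silkcnv.validation import gc_correction_metrics

metrics = gc_correction_metrics(seed=1, amplitude=0.3)
print(f"bins analysed:              {metrics['n_bins']}")
print(f"count-vs-GC slope, raw:     {metrics['slope_raw']:8.1f} counts per GC unit")
print(f"count-vs-GC slope, LOESS:   {metrics['slope_corrected']:8.1f}")
print(f"slope reduction:            {metrics['slope_reduction_fold']:.1f}-fold")
print(
    f"null run, max bin change:   {100 * metrics['null_max_relative_change']:.2f}%"
)
print(
    "\nA >= 5-fold slope reduction with sub-5% distortion of unbiased counts"
    "\nmeans the correction removes the injected trend without inventing one."
)
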