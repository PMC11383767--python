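"""Model construction and parameter accounting.

Builds the baseline windowed-attention classifier and the improved variant
(input residual module + per-stage skip fusion with residual re-processing)
and prints their trainable-parameter counts in units of ten thousand, plus
the attention complexity comparison for the first stage's token grid.
"""

from resswin import (ImprovedModelConfig, ResidualSwinClassifier, SwinClassifier,
                     SwinConfig, attention_flops, count_parameters)

baseline = SwinClassifier(SwinConfig(), 0)
improved = ResidualSwinClassifier(ImprovedModelConfig())

nb, ni = count_parameters(baseline), count_parameters(improved)
print(f"baseline: {nb:>10,} parameters  ({nb / 1e4:.2f} x 10^4)")
print(f"improved: {ni:>10,} parameters  ({ni / 1e4:.2f} x 10^4)")
print(f"input residual module (7x7 convs, 3 channels): "
      f"{count_parameters(improved.module1):,}")
print(f"stage residual modules (3x3 convs at 96/192/384/768): "
      f"{sum(count_parameters(m) for m in improved.module2):,}")
# the increments (+900 and +14,109,120) are exactly the published rises in
# the model-size ablation; the skips themselves add zero parameters.

H = W = 56  # first-stage token grid of a 224 input with 4x4 patches
C, M = 96, 7
print(f"\nglobal attention MACs at {H}x{W}x{C}:   {attention_flops(H, W, C):,}")
print(f"windowed (M={M}) attention MACs:         "
      f"{attention_flops(H, W, C, M, windowed=True):,}")
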