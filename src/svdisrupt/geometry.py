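"""Predictor geometry: input span, bin width, output bins, crop."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PredictorGeometry:
    """Geometry of a sequence-to-contact-map predictor.

    The model reads ``input_span_bp`` of sequence and emits a square map of
    ``n_bins`` bins of ``bin_bp`` bp covering the central ``output_span_bp``,
    after cropping ``crop_bins_per_side`` bins from each side:

        input_span_bp = (n_bins + 2 * crop_bins_per_side) * bin_bp

    Defaults match the published 1 Mb-window model: 1,048,576 bp in,
    448 x 2,048 bp bins (917,504 bp) out.
    """

    input_span_bp: int = 1_048_576
    bin_bp: int = 2_048
    n_bins: int = 448
    crop_bins_per_side: int = 32

    def __post_init__(self) -> None:
        expect = (self.n_bins + 2 * self.crop_bins_per_side) * self.bin_bp
        if expect != self.input_span_bp:
            raise ValueError(
                f"inconsistent geometry: (n_bins + 2*crop) * bin_bp = {expect} "
                f"!= input_span_bp = {self.input_span_bp}"
            )

    @property
    def output_span_bp(self) -> int:
        return self.n_bins * self.bin_bp

    @property
    def crop_bp(self) -> int:
        return self.crop_bins_per_side * self.bin_bp


#: Small geometry for exhaustive tests: 16 bins of 4 bp in, 8 bins out.
TOY_GEOMETRY = PredictorGeometry(input_span_bp=64, bin_bp=4, n_bins=8, crop_bins_per_side=4)
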