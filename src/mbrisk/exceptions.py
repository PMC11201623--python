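"""Exception types raised across the pipeline."""


class DegenerateShapeError(ValueError):
    """Mask or surface too small/ill-formed to support the requested geometry."""


class DegenerateHistogramError(ValueError):
    """Intensity histogram has no usable spread (e.g. constant image)."""


class UndefinedConcordanceError(ValueError):
    """No permissible pairs: Harrell's C is undefined."""


__all__ = [
    "DegenerateShapeError",
    "DegenerateHistogramError",
    "UndefinedConcordanceError",
]
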