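"""Exception types shared across the pipeline."""


class SegmentationError(RuntimeError):
    """Raised when a segmentation stage cannot isolate the expected region.

    ``region`` names the stage that failed (``"section"``, ``"outer"``,
    ``"core"``, ``"locule"`` or ``"fruit"``).
    """

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"segmentation failed for region '{region}'")


class InvalidSignalError(ValueError):
    """Raised when an e-nose curve violates signal preconditions.

    Most commonly a non-positive baseline estimate, which makes the
    fractional-change normalization Ys(t) = (Xs(t) - Xs(0)) / Xs(0) undefined.
    """
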