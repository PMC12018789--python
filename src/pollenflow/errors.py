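"""Exception types shared across the pipeline."""


class PollenflowError(Exception):
    """Base class for pipeline errors."""


class EmptyObjectError(PollenflowError):
    """No pixel in the image exceeds the minimum-contrast floor."""


class EmptyMaskError(PollenflowError):
    """A feature was requested on an empty mask."""


class FeatureError(PollenflowError):
    """A feature is undefined for this mask (e.g. too few boundary pixels)."""


class TreeError(PollenflowError):
    """Invalid phylogeny input (missing branch lengths, duplicate or absent tips)."""
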