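"""Labelled exception hierarchy for pollicolor."""


class PollicolorError(Exception):
    """Base class for all package errors."""


class SpectrumError(PollicolorError):
    """Malformed or incompatible reflectance spectra."""


class VisionError(PollicolorError):
    """Visual-model precondition violations (catches, loci, viewers)."""


class StatsError(PollicolorError):
    """Bootstrap / permutation precondition violations."""


class TreeError(PollicolorError):
    """Tree parsing or topology problems."""


class FitError(PollicolorError):
    """Model-fitting failures (non-finite optima, singular covariance)."""


class ConfigError(PollicolorError):
    """Pipeline configuration validation failures."""
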