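"""Exception hierarchy shared across the pipeline."""


class RecessmapError(Exception):
    """Base class for all errors raised by recessmap."""


class FormatError(RecessmapError):
    """A file does not conform to the expected text format."""


class ConfigurationError(RecessmapError):
    """Inputs are individually valid but mutually inconsistent (missing samples,
    empty phenotype classes, interval/signature mismatches, ...)."""


class SimulationError(RecessmapError):
    """The gene-drop simulation cannot satisfy the requested study design."""


class UndefinedFrequencyError(RecessmapError):
    """An allele frequency is requested at a marker with zero typed animals."""


class UnsupportedVariantError(RecessmapError):
    """A variant class (e.g. an indel) is outside the SNV-only consequence model."""
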