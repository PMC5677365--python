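"""Exception and warning types shared across the pipeline."""


class SisterH3Error(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SisterH3Error):
    """Malformed input file (missing header, wrong columns, bad cell)."""


class UniquenessError(FormatError):
    """Duplicate gene or sample identifier in an input table."""


class DesignError(SisterH3Error):
    """Sample sheet is inconsistent with the requested analysis."""


class PairingError(DesignError):
    """A starved (T1) sample lacks its pre-starvation (T0) partner."""


class ConfigError(SisterH3Error):
    """Invalid configuration value (threshold, proportion, method name)."""


class InputError(SisterH3Error):
    """Fatal data problem, e.g. the reference gene is zero or absent."""


class DegenerateEndpointsError(SisterH3Error):
    """WT and double-mutant fold-changes coincide; Mid is undefined."""


class InsufficientDataError(SisterH3Error):
    """Too few usable genes or replicates for the requested statistic."""


class ClassificationWarning(UserWarning):
    """Non-fatal classification issue (e.g. empty Cluster II, skipped gene)."""
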