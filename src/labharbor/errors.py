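"""Exception hierarchy shared by all pipeline stages."""


class LabHarborError(Exception):
    """Base class for all labharbor errors."""


class SchemaError(LabHarborError):
    """A file or table does not conform to the expected schema."""


class IntegrityError(LabHarborError):
    """Data violate an integrity constraint (duplicates, collisions)."""


class FormatError(LabHarborError):
    """A raw input file does not match its declared layout."""


class ConfigError(LabHarborError):
    """A configuration value references something that does not exist."""


class DataError(LabHarborError):
    """Record-level data are internally inconsistent (e.g. death before
    diagnosis)."""


class DeidentificationError(LabHarborError):
    """A patient key could not be replaced by a registry record_id.

    Messages never contain the patient key itself, only source-row
    provenance.
    """


class DegenerateFitError(LabHarborError):
    """A model fit is impossible (constant covariate, no events)."""
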