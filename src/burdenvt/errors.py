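"""Exception hierarchy for burdenvt.

Parse/config errors (user-fixable input problems) are kept distinct from
analysis errors so the CLI can map them to exit code 2 vs 1.
"""


class BurdenvtError(Exception):
    """Base class for all burdenvt errors."""


class ParseError(BurdenvtError):
    """A table or config file could not be parsed; message names the location."""


class ReferentialIntegrityError(ParseError):
    """A genotype entry references an unknown individual or variant."""


class DuplicateEntryError(ParseError):
    """A (individual, variant) genotype pair or an id occurs more than once."""


class ConfigError(BurdenvtError):
    """An analysis configuration is invalid or internally inconsistent."""


class LookupError_(BurdenvtError):
    """A named variant, region or cohort does not exist."""


class DegenerateInputError(BurdenvtError):
    """An analysis was requested on data that cannot support it
    (e.g. empty case or control arm, zero MAF reference individuals)."""


class MergeError(BurdenvtError):
    """Two cohorts cannot be merged (id collision or conflicting annotation)."""
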