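"""Exception hierarchy for the ercnet pipeline."""


class ErcError(Exception):
    """Base class for all ercnet errors."""


class FormatError(ErcError):
    """Unparseable or malformed input (newick, table, matrix file)."""


class LabelError(ErcError):
    """A leaf or gene label that is not in the reference universe."""


class TopologyConflictError(ErcError):
    """A gene tree contains a split incompatible with the reference topology."""


class EmptyResultError(ErcError):
    """A filtering step removed every record."""


class InsufficientDataError(ErcError):
    """Too few present genes / defined pairs to compute a statistic."""


class DegeneratePairError(ErcError):
    """A disease pair with no genes left after dropping shared members."""


class IntegrityError(ErcError):
    """A stored matrix failed its checksum on load (strict mode)."""
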