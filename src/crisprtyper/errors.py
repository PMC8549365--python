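"""Typed exceptions shared across the package."""


class CrisprTyperError(Exception):
    """Base class for all package errors."""


class CollinearityError(CrisprTyperError):
    """Shared spacers occur in discordant order in the two arrays.

    Under ordered insertion at the leader and independent loss, the relative
    order of spacers retained in both lineages is always preserved; a
    discordant pair is inconsistent with the model and we fail loudly.
    """


class NoRepeatFound(CrisprTyperError):
    """No read contains the CRISPR repeat within the allowed edit distance."""


class EmptySample(CrisprTyperError):
    """A sample yielded zero PASS reads, so no haplotype can be called."""


class DomainError(CrisprTyperError):
    """Model parameter outside its domain (negative time or rate ratio)."""


class NoSharedSpacers(CrisprTyperError):
    """Two arrays share no spacer; divergence time is unidentifiable."""


class InvalidMatrix(CrisprTyperError):
    """Distance matrix violates symmetry / non-negativity / zero diagonal."""


class DegenerateDesign(CrisprTyperError):
    """A hierarchy level has too few groups for its variance component."""


class TooFewEntries(CrisprTyperError):
    """Matrix correlation left with fewer than three usable pairs."""


class UndefinedCorrelation(CrisprTyperError):
    """Correlation undefined because one matrix has zero variance."""


class Disconnected(CrisprTyperError):
    """Minimum spanning network input graph is not connected."""


class PositionOutOfRange(CrisprTyperError):
    """Requested SNP column lies outside the alignment."""


class ExtinctArray(CrisprTyperError):
    """A simulated lineage lost every spacer (after the retry cap)."""
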