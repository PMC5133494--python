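"""Exception hierarchy for treescan.

All domain errors derive from :class:`TreescanError` and from ``ValueError``
so that callers can catch either the package-specific or the generic class.
"""


class TreescanError(Exception):
    """Base class for all treescan errors."""


class InvalidArgumentError(TreescanError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedInputError(TreescanError, ValueError):
    """Input data is outside the supported formats (unphased or missing GT, ...)."""


class EmptyRegionError(TreescanError, ValueError):
    """A gene region contains no analyzable SNP after filtering."""


class DegenerateTraitError(TreescanError, ValueError):
    """The trait carries no variance under the fitted model (sigma2_hat = 0)."""


class DegenerateTreeError(TreescanError, ValueError):
    """The local tree has zero height or admits no valid cluster count."""


class DegenerateDesignError(TreescanError, ValueError):
    """The GLS design matrix X' V^-1 X is singular."""


class UnstableTestError(TreescanError, ValueError):
    """An allelic group holds fewer than 2 observations; the t-test is skipped."""
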