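"""Exception types shared across the package.

Usage errors (bad labels, malformed arguments) raise plain ``ValueError``;
the classes here mark structural, resource, or domain-specific failures.
"""


class SynergyNetError(Exception):
    """Base class for package-specific errors."""


class StructureError(SynergyNetError):
    """The network graph is structurally invalid (e.g. contains a cycle)."""


class ResourceError(SynergyNetError):
    """Exact computation refused because the problem is too large."""


class DesignError(SynergyNetError):
    """A synergistic CPT cannot be designed for the given parent distribution."""


class InterventionError(SynergyNetError):
    """The requested intervention is not well defined on this network."""


class ParseError(SynergyNetError):
    """A file did not conform to the expected on-disk format."""
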