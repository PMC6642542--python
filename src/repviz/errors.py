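"""Exception hierarchy. Everything user-facing derives from RepVizError so
the CLI can catch one type and print one message."""


class RepVizError(Exception):
    """Base class for all errors raised by repviz."""


class RegionParseError(RepVizError, ValueError):
    """A region string could not be interpreted."""


class ConfigError(RepVizError):
    """A CSV configuration file is malformed or references missing inputs."""


class CoverageError(RepVizError):
    """Coverage could not be computed from a BAM input."""


class TrackError(RepVizError):
    """A BED or GTF track file is malformed."""


class RenderError(RepVizError):
    """The figure specification is invalid or cannot be written."""


class FixtureError(RepVizError):
    """A synthetic fixture specification is inconsistent."""
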