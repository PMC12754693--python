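"""Exception hierarchy.

Distinct error classes so callers (and the CLI) can separate I/O problems,
degenerate geometry, correspondence/layout mismatches, undefined statistics
and configuration schema violations.
"""


class FootSSMError(Exception):
    """Base class for all package errors."""


class MeshIOError(FootSSMError):
    """A mesh file could not be read or written."""


class UnsupportedFormatError(MeshIOError):
    """File extension is not one of the supported mesh formats."""


class EmptyMeshError(MeshIOError):
    """A parsed mesh contains no vertices or no faces."""


class DegenerateGeometryError(FootSSMError):
    """Geometry does not support the requested operation.

    Raised for rank-deficient point sets, near-spherical bones without a
    well-defined longitudinal axis, collinear ICP input, and similar.
    """


class CorrespondenceError(FootSSMError):
    """Particle layouts or template topologies do not match across subjects."""


class StatisticsError(FootSSMError):
    """A statistic is undefined for the given input (zero variance, singular
    covariance, group too small)."""


class ConfigError(FootSSMError):
    """Configuration schema violation.

    Carries the full list of problems, not just the first one found.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
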