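"""Exception hierarchy for cathsim."""


class CathsimError(Exception):
    """Base class for all cathsim errors."""


class InvalidScenarioError(CathsimError):
    """Requested scenario id is not one of 1-4 or 'free'."""


class IncompleteEnvironmentError(CathsimError):
    """Environment lacks a landmark or waypoint chain required by a scenario."""


class ScenarioFormatError(CathsimError):
    """Scenario/environment JSON violates the schema; message names the field."""


class UnroutableError(CathsimError):
    """No path connects two landmarks in the cognitive-map graph."""


class InvalidParameterError(CathsimError):
    """Geometry or configuration parameter out of range."""


class UnsupportedShapeError(CathsimError):
    """Organ primitive shape without a closed-form distance."""


class MisconfiguredModeError(CathsimError):
    """Collision check invoked with neither a fixture nor organs."""


class InvalidCommandError(CathsimError):
    """Controller command is non-finite."""


class UnbalancedDesignError(CathsimError):
    """Long table is not a balanced subject x repetition design."""


class MissingGroupError(CathsimError):
    """A required group has no rows in the table."""
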