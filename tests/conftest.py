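import pytest
from hypothesis import HealthCheck, settings

from mibot import (
    EngineConfig,
    KeywordEntry,
    MISkill,
    ResponseTemplate,
    Script,
    ScriptSpec,
    generate_fixture_script,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_script() -> Script:
    """Fixture script at the reference scale (70 categories, full pools)."""
    return generate_fixture_script(ScriptSpec(seed=0), ensure_session=EngineConfig())


@pytest.fixture(scope="session")
def default_config() -> EngineConfig:
    return EngineConfig()


def make_tiny_script() -> Script:
    """A minimal hand-built script: 1 category, 1 template per pool."""
    templates = {
        "gi-open-000": ResponseTemplate("gi-open-000", MISkill.GI, "Hello, let's talk."),
        "gi-close-000": ResponseTemplate("gi-close-000", MISkill.GI, "Goodbye for now."),
        "fq-000": ResponseTemplate("fq-000", MISkill.FQ, "What bothers you most?"),
        "eq-000": ResponseTemplate("eq-000", MISkill.EQ, "What would you change?"),
        "r-000": ResponseTemplate("r-000", MISkill.R, "That sounds hard."),
        "mia-000": ResponseTemplate("mia-000", MISkill.MIA, "You are doing your best."),
        "fb-000": ResponseTemplate("fb-000", MISkill.FALLBACK, "Tell me more."),
    }
    category = KeywordEntry(
        keyword="school",
        weight=3,
        responses={
            MISkill.FQ: ["fq-000"],
            MISkill.EQ: ["eq-000"],
            MISkill.R: ["r-000"],
            MISkill.MIA: ["mia-000"],
        },
    )
    return Script(
        metadata={"name": "tiny", "version": "1"},
        templates=templates,
        categories=[category],
        gi_opening=["gi-open-000"],
        gi_closing=["gi-close-000"],
        fallbacks=["fb-000"],
    )


@pytest.fixture()
def tiny_script() -> Script:
    return make_tiny_script()
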