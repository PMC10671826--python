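import datetime as dt

import pytest

from hhcteams import (TeamDemandModel, VisitRecord, load_team_parameters)


@pytest.fixture(scope="session")
def builtin_teams():
    """The built-in nine-team parameter table, keyed by team id."""
    return {t.team_id: t for t in load_team_parameters()}


@pytest.fixture(scope="session")
def team_models(builtin_teams):
    """Demand models for the nine built-in teams."""
    return {tid: TeamDemandModel.from_team_parameters(tp)
            for tid, tp in builtin_teams.items()}


def make_visit(client="c1", team="T1", date=dt.date(2021, 1, 4),
               part="morning", hours=1.0, ql=1, **kw):
    """Shorthand visit-record factory for tests."""
    return VisitRecord(client_id=client, team_id=team, date=date,
                       day_part=part, duration=hours,
                       qualification_level=ql, **kw)
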