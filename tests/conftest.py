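"""Shared fixtures: toy registries built in memory, small generated ones."""

from datetime import date

import pandas as pd
import pytest

from agemix import RegistryConfig, generate_registry


def make_tx_row(i, **overrides):
    """One well-formed transplant record with overridable fields."""
    row = {
        "tx_id": f"T{i:04d}",
        "tx_date": pd.Timestamp("2015-06-01"),
        "donor_id": f"D{i:04d}",
        "recipient_id": f"R{i:04d}",
        "donor_age": 16,
        "donor_sex": "M",
        "donor_height": 170.0,
        "donor_weight": 65.0,
        "donor_type": "DBD",
        "donor_hospital": "H0001",
        "recipient_age": 15,
        "recipient_sex": "F",
        "recipient_height": 160.0,
        "recipient_weight": 55.0,
        "recipient_category": "adolescent",
        "diagnosis": "biliary_atresia",
        "meld": 18,
        "status1": False,
        "admission": "home",
        "prior_transplant": False,
        "multiorgan": False,
        "graft_type": "whole",
        "cit_hours": 6.5,
        "center_id": "H0001",
        "recipient_hospital": "H0001",
        "waiting_days": 40,
        "graft_loss_date": pd.NaT,
        "death_date": pd.NaT,
        "last_followup_date": pd.Timestamp("2024-06-01"),
    }
    row.update(overrides)
    return row


@pytest.fixture
def tx_row_factory():
    return make_tx_row


@pytest.fixture(scope="session")
def small_registry():
    """Moderate synthetic registry shared across read-only tests."""
    cfg = RegistryConfig(n_adolescent_tx=4000,
                         n_adult_tx_of_adolescent_grafts=2000, seed=42)
    hospitals, adolescent, adult = generate_registry(cfg)
    return cfg, hospitals, adolescent, adult
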