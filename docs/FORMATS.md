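# File formats

Units are part of column names; no silent conversion is performed
anywhere. All CSV numeric payloads are written with 17 significant digits
and read back with round-trip float parsing, so write→read is
bit-faithful.

## Waveform CSV (`read_waveform_csv` / `write_waveform_csv`)

First line: `# period_s=<float>`. Then a CSV table:

| column      | meaning                        |
|-------------|--------------------------------|
| `time_s`    | sample instant, s; starts at 0, strictly increasing, < period |
| `flow_mL_s` | volumetric flow, mL/s          |

The waveform is extended periodically (value at `period` = value at 0).

## WK3 parameter table (`read_wk3_table` / `write_wk3_table`)

| column                 | meaning                                  |
|------------------------|------------------------------------------|
| `outlet`               | outlet name                              |
| `R_tot_mmHg_per_mL_s`  | total resistance, mmHg/(mL/s), > 0       |
| `rho`                  | proximal fraction, in (0, 1)             |
| `R_p_mmHg_per_mL_s`    | proximal resistance (written, not read)  |
| `R_d_mmHg_per_mL_s`    | distal resistance (written, not read)    |
| `C_mL_per_mmHg`        | compliance, mL/mmHg, > 0                 |

Rows violating the parameter invariants raise with the 1-based file row
number.

## Plane series CSV (`read_plane_series_csv` / `write_plane_series_csv`)

First line: `# period_s=<float>`. Long format, one row per sample per
frame; frames are grouped by `t_s`:

`x_mm, y_mm, z_mm, vx_m_s, vy_m_s, vz_m_s, area_mm2, t_s, nx, ny, nz`

`(nx, ny, nz)` is the frame's unit plane normal, repeated on each row of
the frame.

## Plane series HDF5 (`read_plane_series_h5` / `write_plane_series_h5`)

Root attribute `period_s`; groups `frame_0000`, `frame_0001`, … each with
attribute `t_s` and datasets `points_mm (n,3)`, `velocities_m_s (n,3)`,
`area_mm2 (n,)`, `normal (3,)`.

## WSS history HDF5 (`read_wss_history_h5` / `write_wss_history_h5`)

Datasets `node_ids (n,)`, `times_s (m,)` (uniform grid), `tau_Pa (n,m,3)`.

## Legacy-VTK point-data export (`export_vtk_pointdata`)

ASCII legacy polydata: `POINTS n double`, one `VERTICES` cell per point,
then `POINT_DATA n` with one `SCALARS <name> double 1` +
`LOOKUP_TABLE default` block per map (e.g. `TAWSS`, `OSI`, `ECAP`).

## Study config YAML (`load_study`)

Schema-validated (unknown keys rejected). Top level: `name`,
`heart_rate_bpm`, `brachial_systolic_mmHg`, `brachial_diastolic_mmHg`,
`seed`, `solver` (`dt_s`, `convergence_threshold`, `max_cycles`,
`venous_pressure_mmHg`), `metrics` (`wss_sampling_interval_s`,
`ecap_threshold_per_Pa`), `viscosity` (Carreau–Yasuda constants +
density), `cases` (mapping case name → `outlets` list), and
`minor_branch_groups` (mapping group → `n_branches`, `total_flow_mL_s`).

Outlet entry fields: `name`, `lumen` (`TL`|`FL`|`none`), `rho`,
`n_branches`, and optionally `target_flow_mL_s`, `measured_flow_mL_s`,
`cfd_flow_mL_s`, `R_tot_mmHg_per_mL_s`, `C_mL_per_mmHg`.

## CLI artifacts

Every subcommand writes `<command>_run.json` with the command name,
package version, config hash and seed next to its outputs
(`flow_targets.csv`, `pressure_targets.csv`, `wk3_parameters.csv`,
`tuning_report.json`, `outlet_mean_flows.csv`, `traces.csv`,
`cycle_summary.json`, `manifest.json`, `wss_indices.csv`,
`wss_indices.vtk`, `metrics_report.json`, `study_report.json`).
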