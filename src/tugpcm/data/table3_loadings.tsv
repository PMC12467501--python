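parameter	pc1	pc2	pc3	pc4	pc5	pc6	pc7	pc8	pc9	pc10	pc11
explained_variance_pct	22.21	11.31	9.18	7.34	6.57	5.86	5.45	4.98	4.31	3.70	3.42
hip_sagittal_rom_deg_walk_back	0.877	0.062	0.015	0.036	0.079	-0.036	-0.215	-0.018	-0.054	0.161	-0.041
hip_sagittal_velocity_range_deg_s_walk_back	0.865	0.049	-0.113	0.179	0.154	-0.03	-0.259	0.118	0.114	0.089	0.091
com_vertical_velocity_range_m_s_walk_back	0.864	0.043	0.094	0.056	0.056	-0.067	0.174	0.057	0.189	-0.079	0.066
hip_sagittal_rom_deg_walk_forward	0.855	0.034	-0.266	-0.017	0.045	-0.004	0.008	0.117	-0.041	0.08	0.057
knee_sagittal_velocity_range_deg_s_walk_forward	0.826	-0.007	-0.159	0.074	0.116	0.066	0.055	0.134	0.133	0.004	0.035
com_ap_velocity_range_m_s_turn	0.816	0.027	-0.175	-0.039	0.04	-0.153	0.188	0.198	0.154	0.094	0.11
com_vertical_velocity_range_m_s_turn	0.812	0.05	-0.099	0.052	0.006	-0.112	0.224	0.046	0.186	-0.156	0.085
trunk_frontal_velocity_range_deg_s_turn	-0.063	0.950	0.022	0.043	-0.056	0.081	-0.023	-0.013	-0.008	0.01	0.02
trunk_sagittal_velocity_range_deg_s_turn	-0.08	0.933	-0.036	0.099	0.075	0.177	-0.056	-0.037	0.006	0.025	0.074
trunk_frontal_rom_deg_turn	0.157	0.833	0.063	-0.013	-0.121	0.034	0.182	0.017	-0.096	-0.021	-0.015
knee_sagittal_velocity_range_deg_s_sit_to_walk	-0.075	0.019	0.892	0.078	-0.017	0.018	-0.04	-0.045	0.094	0.139	0.016
hip_sagittal_rom_deg_sit_to_walk	-0.218	-0.026	0.852	0.065	0.164	0.144	0.068	-0.018	-0.033	-0.127	0.03
trunk_sagittal_velocity_range_deg_s_walk_back	-0.094	0.075	0.151	0.917	0.077	-0.048	-0.043	-0.118	-0.063	-0.131	-0.031
trunk_frontal_velocity_range_deg_s_walk_back	0.014	0.067	0.161	0.904	-0.021	-0.08	0.057	0.095	-0.076	-0.039	0.032
trunk_transverse_velocity_range_deg_s_walk_back	0.307	-0.038	-0.038	0.816	0.044	-0.162	-0.032	-0.076	0.087	0.021	-0.089
knee_transverse_velocity_range_deg_s_turn	0.188	-0.014	-0.008	0.059	0.904	-0.05	0.013	0.132	-0.044	-0.03	0.115
knee_transverse_rom_deg_turn	0.102	-0.074	0.132	0.049	0.853	-0.079	-0.044	0.004	-0.093	0.122	-0.147
knee_frontal_rom_deg_turn	0.045	0.195	-0.047	0.041	0.819	-0.166	-0.098	0.014	0.08	0.162	0.016
trunk_sagittal_velocity_range_deg_s_sit_to_walk	-0.102	0.047	0.05	-0.101	-0.113	0.873	0.116	-0.019	0.084	0.02	0.113
trunk_frontal_velocity_range_deg_s_sit_to_walk	0.023	0.165	0.06	-0.042	-0.111	0.846	-0.167	0.043	-0.073	0.04	-0.068
trunk_transverse_velocity_range_deg_s_sit_to_walk	-0.131	0.211	0.017	-0.056	-0.048	0.814	-0.056	0.077	-0.002	-0.124	0.115
com_vertical_displacement_m_turn_to_sit	-0.038	0.091	0.154	0.038	-0.09	-0.12	0.878	0.015	-0.135	-0.083	0.053
com_ml_displacement_m_turn	0.216	0.068	-0.035	-0.105	0.086	0.03	-0.024	0.932	0.103	-0.024	-0.008
com_ml_displacement_m_walk_back	0.146	-0.119	-0.092	0.047	0.097	0.04	0.068	0.899	0.013	-0.059	-0.054
ankle_transverse_velocity_range_deg_s_walk_forward	0.215	-0.101	0.001	-0.009	0.087	-0.023	0.007	-0.002	0.918	0.085	-0.02
ankle_transverse_rom_deg_walk_forward	0.255	0.014	-0.005	0.002	-0.181	0.032	-0.073	0.150	0.883	0.036	-0.005
hip_transverse_rom_deg_walk_forward	-0.012	0.048	0.021	-0.004	0.071	0.015	0.001	-0.067	-0.03	0.911	0.076
hip_transverse_velocity_range_deg_s_walk_forward	0.137	-0.04	-0.01	-0.074	0.16	-0.077	0.027	0.032	0.16	0.887	0.071
hip_transverse_rom_deg_walk_back	0.077	0.054	0.003	0.008	-0.129	0.129	-0.058	-0.065	-0.086	0.076	0.882
hip_transverse_velocity_range_deg_s_walk_back	0.230	0.061	0.048	-0.113	0.131	0.012	0.100	0.013	0.064	0.073	0.875
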