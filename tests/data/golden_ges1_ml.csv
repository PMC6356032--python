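equipment,model,formulation,environment,group,ppe,rpe,population,dermal_mg_per_kg_bw_day,inhalation_mg_per_m3,rcr_dermal,rcr_inhalation,rcr_total,worst_case
mixing and loading tractor-mounted/trailed boom sprayer,BBA,liquid,-,tractor,No PPE,No RPE,worker,0.79277844912,0.00139960886352,0.26425948304,0.000127237169411,0.26438672021,False
mixing and loading tractor-mounted/trailed boom sprayer,BBA,WP,-,tractor,No PPE,No RPE,worker,1.98144626249,0.161754795798,0.660482087497,0.0147049814362,0.675187068934,True
mixing and loading tractor-mounted/trailed boom sprayer,BBA,WG,-,tractor,No PPE,No RPE,worker,0.660815327703,0.0184948314108,0.220271775901,0.00168134831007,0.221953124211,False
mixing and loading tractor-mounted/trailed broadcast air-assisted sprayer,BBA,liquid,-,tractor,No PPE,No RPE,worker,0.317111379648,0.000559843545407,0.105703793216,5.08948677642e-05,0.105754688084,False
mixing and loading tractor-mounted/trailed broadcast air-assisted sprayer,BBA,WP,-,tractor,No PPE,No RPE,worker,0.792578504997,0.0647019183191,0.264192834999,0.00588199257447,0.270074827573,False
mixing and loading tractor-mounted/trailed broadcast air-assisted sprayer,BBA,WG,-,tractor,No PPE,No RPE,worker,0.264326131081,0.0073979325643,0.0881087103604,0.000672539324027,0.0887812496844,False
mixing and loading hand-held sprayer,BBA,liquid,-,hand_held,No PPE,No RPE,worker,2.24957564899,0.00380097263946,0.749858549663,0.000345542967224,0.75020409263,True
mixing and loading hand-held sprayer,BBA,WP,-,hand_held,No PPE,No RPE,worker,0.549140520807,0.0614157158061,0.183046840269,0.00558324689146,0.18863008716,False
mixing and loading hand-held sprayer,BBA,WG,-,hand_held,No PPE,No RPE,worker,0.230058870283,0.00150038393663,0.0766862900944,0.000136398539694,0.0768226886341,False
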