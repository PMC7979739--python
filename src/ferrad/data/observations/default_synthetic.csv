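protocol,observable,value,uncertainty,rh,mr,thickness_um,time_s
edb,radius_loss_fraction,0.12,0.01,50.0,0.05,,
edb,mass_loss_fraction,0.33,0.04,50.0,0.05,,
edb,radius_loss_fraction,0.00375,0.0019,16.0,0.05,,
cwft,p_ho2,3.9e10,3.9e9,38.5,0.0784,0.18,
cwft,p_ho2,1.3e11,1.3e10,38.5,0.0784,0.89,
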