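material,kind,energy_keV,mu_over_rho_cm2_g
tungsten,attenuation,10.0,96.91
tungsten,attenuation,15.0,139.0
tungsten,attenuation,20.0,65.73
tungsten,attenuation,30.0,22.73
tungsten,attenuation,40.0,10.67
tungsten,attenuation,50.0,5.949
tungsten,attenuation,60.0,3.713
tungsten,attenuation,69.52,2.552
tungsten,attenuation,69.53,11.23
tungsten,attenuation,80.0,7.810
tungsten,attenuation,100.0,4.438
tungsten,attenuation,150.0,1.581
beryllium,attenuation,10.0,0.6466
beryllium,attenuation,15.0,0.3070
beryllium,attenuation,20.0,0.2251
beryllium,attenuation,30.0,0.1792
beryllium,attenuation,40.0,0.1640
beryllium,attenuation,50.0,0.1554
beryllium,attenuation,60.0,0.1493
beryllium,attenuation,80.0,0.1401
beryllium,attenuation,100.0,0.1328
beryllium,attenuation,150.0,0.1190
air,energy-absorption,10.0,4.742
air,energy-absorption,15.0,1.334
air,energy-absorption,20.0,0.5389
air,energy-absorption,30.0,0.1537
air,energy-absorption,40.0,0.06833
air,energy-absorption,50.0,0.04098
air,energy-absorption,60.0,0.03041
air,energy-absorption,80.0,0.02407
air,energy-absorption,100.0,0.02325
air,energy-absorption,150.0,0.02496
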