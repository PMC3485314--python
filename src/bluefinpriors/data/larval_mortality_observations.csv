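species,age_days,age_reference,kind,mortality,source
Thunnus thynnus,3,post-hatching,instantaneous_daily,0.2,Scott et al. (1993)
Thunnus thynnus,10,post-hatching,instantaneous_daily,0.2,Scott et al. (1993)
Thunnus albacares,3,dpef,instantaneous_daily,0.16,Lang et al. (1994)
Thunnus albacares,14,dpef,instantaneous_daily,0.41,Lang et al. (1994)
Thunnus maccoyii,11,post-hatching,instantaneous_daily,0.68,Davis et al. (1991)
Thunnus maccoyii,12,post-hatching,instantaneous_daily,0.97,Davis et al. (1991)
Thunnus orientalis,5,post-hatching,instantaneous_daily,1.66,Satoh et al. (2008)
Thunnus orientalis,6,post-hatching,instantaneous_daily,2.41,Satoh et al. (2008)
Thunnus orientalis,7,post-hatching,instantaneous_daily,2.75,Satoh et al. (2008)
Thunnus orientalis,8,post-hatching,instantaneous_daily,0.06,Satoh et al. (2008)
Thunnus orientalis,9,post-hatching,instantaneous_daily,1.74,Satoh et al. (2008)
Thunnus orientalis,11,post-hatching,instantaneous_daily,1.52,Satoh et al. (2008)
Thunnus orientalis,12,post-hatching,instantaneous_daily,1.52,Satoh et al. (2008)
Scomber scombrus,11.42,post-hatching,cumulative,6.02,Ware and Lambert (1985)
Scomber scombrus,17.3,post-hatching,cumulative,8.14,Ware and Lambert (1985)
Engraulis encrasicolus,100,post-hatching,cumulative,5.99,Allain et al. (2007)
Engraulis encrasicolus,100,post-hatching,cumulative,6.5,Allain et al. (2007)
Engraulis encrasicolus,180,post-hatching,cumulative,9.94,Pertierra et al. (1997)
Engraulis mordax,180,post-hatching,cumulative,9.56,Lo et al. (1995)
Sardinops sagax,180,post-hatching,cumulative,12.25,Lo et al. (1995)
Sardinops caeruleus,180,post-hatching,cumulative,7.88,Lo et al. (1995)
Sardinops caeruleus,180,post-hatching,cumulative,8.465,Lo et al. (1995)
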